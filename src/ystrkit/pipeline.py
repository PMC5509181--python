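"""End-to-end orchestration: load/simulate -> QC filter -> diversity stats
-> LD scan -> pairwise R_ST -> NJ tree + NMDS, with one master seed, a
consolidated JSON + Markdown report, and all stage outputs on disk.

All randomness flows from ``RunConfig.seed`` through fixed per-stage
offsets, and every derived seed is recorded in the provenance block, so a
re-run with the same config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from . import __version__
from .amova import RstConfig, RstResult, filter_for_rst, format_rst_table, rst_matrix
from .core import PopulationDataset, ValidationError
from .diversity import diversity_report
from .ld import ld_matrix
from .phylo import distance_from_rst, neighbor_joining, nmds, sum_branch_lengths, to_newick
from .simulate import SimConfig, simulate_populations
from .ystr_io import (
    dataset_summary,
    read_haplotype_table,
    write_dataset_summary,
    write_haplotype_table,
)

_STAGE_SEED_OFFSETS = {"simulate": 11, "ld": 23, "rst": 37, "mds": 53}


def stage_seed(master_seed: int, stage: str) -> int:
    return (master_seed * 1000003 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Exactly one of ``input_path`` / ``sim`` must be given.  Stage toggles
    let a run stop at, e.g., diversity statistics only.
    """

    out_dir: Union[str, Path] = "ystrkit_run"
    input_path: Optional[Union[str, Path]] = None
    sim: Optional[SimConfig] = None
    panel: str = "y23"
    seed: int = 0
    run_stats: bool = True
    run_ld: bool = True
    run_rst: bool = True
    run_tree: bool = True
    run_mds: bool = True
    ld_permutations: int = 999
    rst_permutations: int = 999
    alpha: float = 0.05
    bonferroni_m: Optional[int] = None
    excluded_loci: Tuple[str, ...] = ()

    def validate(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValidationError("exactly one of input_path / sim must be set")


def _round_matrix(m: np.ndarray, digits: int = 4) -> List[List[float]]:
    return [[round(float(v), digits) for v in row] for row in m]


def run_full_analysis(config: RunConfig) -> Dict[str, object]:
    """Run every enabled stage and write a consolidated report bundle.

    Returns the report dict; artifacts land under ``config.out_dir``:
    ``dataset.tsv``, ``summary.json``, ``diversity.json``, ``ld.tsv``,
    ``rst.tsv`` (report layout: R_ST below the diagonal, P above),
    ``tree.nwk``, ``mds_coords.tsv``, ``report.json``, ``report.md``.
    Stages whose preconditions fail (a single population, say) are skipped
    with an explanatory log entry rather than aborting the run.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: List[str] = []
    report: Dict[str, object] = {}

    # ---- load / simulate -------------------------------------------------
    if config.sim is not None:
        sim = config.sim
        dataset = simulate_populations(sim)
        log.append(f"simulated dataset: {dataset.n} samples, seed {sim.seed}")
    else:
        dataset = read_haplotype_table(config.input_path, panel=config.panel)
        log.append(f"loaded {dataset.n} samples from {config.input_path}")
    write_haplotype_table(dataset, out_dir / "dataset.tsv")
    write_dataset_summary(dataset, out_dir / "summary.json")
    report["dataset"] = dataset_summary(dataset)

    # ---- diversity -------------------------------------------------------
    if config.run_stats:
        div = diversity_report(dataset)
        report["diversity"] = div.rounded()
        (out_dir / "diversity.json").write_text(
            json.dumps(div.rounded(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        log.append(
            f"diversity: {div.k_distinct} distinct haplotypes in {div.n} samples"
        )

    # ---- LD --------------------------------------------------------------
    if config.run_ld:
        ld_res = ld_matrix(
            dataset,
            n_permutations=config.ld_permutations,
            seed=stage_seed(config.seed, "ld"),
            alpha=config.alpha,
        )
        ld_res.to_frame().to_csv(out_dir / "ld.tsv", sep="\t", index=False)
        report["ld"] = {
            "n_pairs": ld_res.n_pairs,
            "n_significant": ld_res.n_significant,
            "percent_significant": ld_res.percent_significant,
            "alpha": ld_res.alpha,
        }
        log.append(
            f"LD: {ld_res.n_significant}/{ld_res.n_pairs} pairs significant "
            f"({ld_res.percent_significant}%)"
        )

    # ---- R_ST ------------------------------------------------------------
    rst_res: Optional[RstResult] = None
    n_pops = len(dataset.populations())
    if config.run_rst:
        if n_pops < 2:
            log.append("R_ST skipped: fewer than 2 populations")
        else:
            rst_cfg = RstConfig(
                n_permutations=config.rst_permutations,
                seed=stage_seed(config.seed, "rst"),
                excluded_loci=config.excluded_loci,
                alpha=config.alpha,
                bonferroni_m=config.bonferroni_m,
            )
            try:
                rst_res = rst_matrix(dataset, rst_cfg)
            except ValidationError as exc:
                log.append(f"R_ST skipped: {exc}")
            if rst_res is not None:
                (out_dir / "rst.tsv").write_text(format_rst_table(rst_res), encoding="utf-8")
                report["rst"] = {
                    "labels": list(rst_res.labels),
                    "rst": _round_matrix(rst_res.rst),
                    "pvals": _round_matrix(rst_res.pvals),
                    "n_comparisons": rst_res.n_comparisons,
                    "bonferroni_threshold": rst_res.bonferroni_threshold,
                    "n_significant_bonferroni": int(rst_res.significant.sum() // 2),
                    "filtered_counts": rst_res.filtered_counts,
                }
                log.append(
                    f"R_ST: {rst_res.n_comparisons} pairs, Bonferroni threshold "
                    f"{rst_res.bonferroni_threshold:.4g}"
                )

    # ---- tree + MDS ------------------------------------------------------
    if rst_res is not None and (config.run_tree or config.run_mds):
        dm = distance_from_rst(rst_res)
        if len(dm.labels) < 3:
            log.append("tree/MDS skipped: fewer than 3 populations")
        else:
            if config.run_tree:
                tree = neighbor_joining(dm)
                newick = to_newick(tree)
                (out_dir / "tree.nwk").write_text(newick + "\n", encoding="utf-8")
                report["tree"] = {
                    "newick": newick,
                    "sum_branch_lengths": sum_branch_lengths(tree),
                    "n_clamped_distances": dm.n_clamped,
                }
                log.append(f"NJ tree: SBL = {sum_branch_lengths(tree):.8f}")
            if config.run_mds:
                mds_res = nmds(dm, seed=stage_seed(config.seed, "mds"))
                coords_rows = ["label\tdim1\tdim2"]
                for lab, (x, y) in zip(mds_res.labels, mds_res.coordinates):
                    coords_rows.append(f"{lab}\t{x:.10g}\t{y:.10g}")
                (out_dir / "mds_coords.tsv").write_text(
                    "\n".join(coords_rows) + "\n", encoding="utf-8"
                )
                report["mds"] = {
                    "stress": float(mds_res.stress),
                    "stress_initial": float(mds_res.stress_initial),
                    "n_iterations": mds_res.n_iterations,
                    "converged": mds_res.converged,
                }
                log.append(f"NMDS: final stress = {mds_res.stress:.5g}")
    elif config.run_tree or config.run_mds:
        log.append("tree/MDS skipped: no R_ST matrix available")

    # ---- provenance + report --------------------------------------------
    report["provenance"] = {
        "ystrkit_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_SEED_OFFSETS},
        "log": log,
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out_dir / "report.md").write_text(_markdown_report(report), encoding="utf-8")
    return report


def _markdown_report(report: Dict[str, object]) -> str:
    lines = ["# ystrkit run report", ""]
    ds = report["dataset"]
    lines += [
        f"- samples: {ds['n_samples']} across {len(ds['populations'])} population(s)",
        f"- loci: {ds['n_loci']} ({ds['n_allele_columns']} allele columns)",
    ]
    if "diversity" in report:
        d = report["diversity"]
        lines += [
            "",
            "## Forensic parameters",
            f"- distinct haplotypes: {d['k_distinct']} / {d['n']} "
            f"({d['k_singleton']} singletons)",
            f"- HD = {d['HD']}, MP = {d['MP']}, DC = {d['DC']}",
        ]
    if "ld" in report:
        l = report["ld"]
        lines += [
            "",
            "## Linkage disequilibrium",
            f"- {l['n_significant']} of {l['n_pairs']} locus pairs significant at "
            f"alpha = {l['alpha']} ({l['percent_significant']}%)",
        ]
    if "rst" in report:
        r = report["rst"]
        lines += [
            "",
            "## Pairwise R_ST",
            f"- {r['n_comparisons']} comparisons, Bonferroni threshold "
            f"{r['bonferroni_threshold']:.4g}",
            f"- significant after correction: {r['n_significant_bonferroni']}",
        ]
    if "tree" in report:
        lines += [
            "",
            "## Neighbor-joining tree",
            f"- sum of branch lengths = {report['tree']['sum_branch_lengths']:.8f}",
        ]
    if "mds" in report:
        m = report["mds"]
        lines += [
            "",
            "## Non-metric MDS",
            f"- final stress = {m['stress']:.5g} (initializer stress "
            f"{m['stress_initial']:.5g}, {m['n_iterations']} iterations)",
        ]
    lines += ["", "## Log", *[f"- {entry}" for entry in report["provenance"]["log"]]]
    return "\n".join(lines) + "\n"
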