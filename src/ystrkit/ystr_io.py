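"""Reading and writing Y-STR haplotype tables and frequency tables.

Input tables are UTF-8 delimited text (tab or comma, autodetected from the
header line) with one row per male sample: a sample-ID column, a population
column, and one column per panel locus.  The DYS385a/b cell holds 1-3
alleles separated by ``,`` or ``-`` (``-`` is the safe choice inside CSV).
Microvariants are written ``16.2``; nulls are written ``0``.

Two panel conventions are enforced here rather than downstream:

* multi-copy allele tuples are sorted ascending on load (DYS385 is an
  unordered pair), and samples with more alleles than the locus copy number
  are loaded but flagged as copy-number variants;
* the DYS389II amplicon contains DYS389I, so the reported DYS389II value is
  converted to a pure repeat count by subtracting DYS389I (on by default,
  recorded in dataset provenance, idempotent).
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .core import (
    Allele,
    AlleleParseError,
    Haplotype,
    LocusDef,
    PopulationDataset,
    SampleRecord,
    ValidationError,
    format_allele,
    get_panel,
    parse_allele,
)

_SAMPLE_ALIASES = ("sample", "sample_id", "sampleid", "id")
_POP_ALIASES = ("population", "pop", "population_label", "group")
_DYS385_ALIASES = ("dys385", "dys385a/b", "dys385ab", "dys385a-b")


def _detect_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def _normalize_colname(name: str) -> str:
    return name.strip().lower().replace(" ", "")


def read_haplotype_table(
    path: Union[str, Path],
    panel: Union[str, Sequence[LocusDef]] = "y23",
    adjust_dys389: bool = True,
) -> PopulationDataset:
    """Load a delimited haplotype table into a :class:`PopulationDataset`.

    Parameters
    ----------
    path:
        Delimited text file (see module docstring for the dialect).
    panel:
        Panel name (``"y23"``) or explicit locus registry.
    adjust_dys389:
        Apply the DYS389II := DYS389II - DYS389I conversion after loading.
    """
    loci = get_panel(panel)
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    delim = _detect_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    norm = [_normalize_colname(c) for c in header]

    def find_col(aliases: Tuple[str, ...], what: str) -> int:
        for alias in aliases:
            if alias in norm:
                return norm.index(alias)
        raise ValidationError(f"{path}: missing {what} column (tried {aliases})")

    sample_col = find_col(_SAMPLE_ALIASES, "sample-ID")
    pop_col = find_col(_POP_ALIASES, "population")
    locus_cols: Dict[str, int] = {}
    for ld in loci:
        aliases = _DYS385_ALIASES if ld.name == "DYS385" else (_normalize_colname(ld.name),)
        locus_cols[ld.name] = find_col(aliases, f"locus {ld.name}")

    records: List[SampleRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(delim)]
        if len(cells) != len(header):
            raise ValidationError(
                f"{path}: row {lineno}: expected {len(header)} fields, got {len(cells)}"
            )
        hap: Haplotype = {}
        cnv: set = set()
        try:
            for ld in loci:
                cell = cells[locus_cols[ld.name]]
                tokens = [t for t in cell.replace("-", ",").split(",") if t.strip()]
                alleles = tuple(sorted(parse_allele(t) for t in tokens))
                if len(alleles) < ld.copy_number:
                    raise ValidationError(
                        f"locus {ld.name}: {len(alleles)} alleles, expected {ld.copy_number}"
                    )
                if len(alleles) > ld.copy_number:
                    cnv.add(ld.name)
                hap[ld.name] = alleles
        except (AlleleParseError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {lineno}: {exc}") from exc
        records.append(
            SampleRecord(
                sample_id=cells[sample_col],
                population=cells[pop_col],
                haplotype=hap,
                cnv_loci=frozenset(cnv),
            )
        )
    dataset = PopulationDataset(
        records, loci, provenance={"source": str(path), "dys389_adjusted": False}
    )
    if adjust_dys389:
        dataset = adjust_dys389_counts(dataset)
    return dataset


def adjust_dys389_counts(dataset: PopulationDataset) -> PopulationDataset:
    """Convert reported DYS389II values to pure repeat counts.

    The DYS389II amplicon spans the DYS389I repeat block, so the reported
    allele is the sum of both; the stored value becomes
    ``DYS389II - DYS389I``.  Idempotent (tracked in provenance).  Records
    with a null at either locus are left unchanged and flagged; a reported
    DYS389II smaller than DYS389I is a validation error, and a zero result
    is kept but flagged as a warning.
    """
    if dataset.provenance.get("dys389_adjusted"):
        return dataset
    names = dataset.locus_names
    if "DYS389I" not in names or "DYS389II" not in names:
        out = PopulationDataset(list(dataset.records), dataset.loci, dict(dataset.provenance))
        out.provenance["dys389_adjusted"] = True
        return out
    new_records: List[SampleRecord] = []
    for rec in dataset.records:
        a1 = rec.haplotype["DYS389I"][0]
        a2 = rec.haplotype["DYS389II"][0]
        if a1.is_null or a2.is_null:
            new_records.append(replace(rec, flags=rec.flags + ("dys389_unadjusted_null",)))
            continue
        if a2.value < a1.value:
            raise ValidationError(
                f"sample {rec.sample_id!r}: reported DYS389II ({a2}) smaller than "
                f"DYS389I ({a1})"
            )
        diff_repeats = a2.repeats - a1.repeats
        flags = rec.flags
        if diff_repeats == 0 and a2.step == 0:
            flags = flags + ("dys389ii_zero_repeats",)
        new_hap = dict(rec.haplotype)
        new_hap["DYS389II"] = (Allele(repeats=diff_repeats, step=a2.step),)
        new_records.append(replace(rec, haplotype=new_hap, flags=flags))
    out = PopulationDataset(new_records, dataset.loci, dict(dataset.provenance))
    out.provenance["dys389_adjusted"] = True
    return out


def _format_cell(alleles: Tuple[Allele, ...], sep: str) -> str:
    return sep.join(format_allele(a) for a in alleles)


def write_haplotype_table(
    dataset: PopulationDataset,
    path: Union[str, Path],
    delimiter: str = "\t",
) -> None:
    """Write a dataset back to a delimited table (DYS385 cell uses ``,`` in
    TSV, ``-`` in CSV).

    Tables always carry the *reported* DYS389II convention (the amplicon
    count including DYS389I), so datasets flagged ``dys389_adjusted`` have
    DYS389I added back on write; re-reading with the default settings then
    reproduces the dataset exactly.
    """
    path = Path(path)
    allele_sep = "," if delimiter == "\t" else "-"
    names = dataset.locus_names
    readd = (
        bool(dataset.provenance.get("dys389_adjusted"))
        and "DYS389I" in names
        and "DYS389II" in names
    )
    header = ["sample_id", "population", *names]
    rows = [delimiter.join(header)]
    for rec in dataset.records:
        cells = [rec.sample_id, rec.population]
        for name in names:
            alleles = rec.haplotype[name]
            if readd and name == "DYS389II" and "dys389_unadjusted_null" not in rec.flags:
                a1 = rec.haplotype["DYS389I"][0]
                a2 = alleles[0]
                if not (a1.is_null or a2.is_null):
                    alleles = (Allele(repeats=a2.repeats + a1.repeats, step=a2.step),)
            cells.append(_format_cell(alleles, allele_sep))
        rows.append(delimiter.join(cells))
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def allele_label(key: object) -> str:
    """Row label for a frequency table entry (``"16.2"``, ``"13-17"``)."""
    if isinstance(key, Allele):
        return format_allele(key)
    if isinstance(key, tuple):
        return "-".join(format_allele(a) for a in key)
    return str(key)


def write_frequency_table(freq_tables, path: Union[str, Path]) -> None:
    """Write per-locus allele frequency tables to a single TSV.

    ``freq_tables`` is a single :class:`~ystrkit.diversity.FrequencyTable`
    or an iterable of them.  Columns: locus, allele, count, frequency (DYS385
    combined pairs use ``a-b`` labels).  Refuses to write unnormalized tables.
    """
    from .diversity import FrequencyTable  # local import to avoid a cycle

    if isinstance(freq_tables, FrequencyTable):
        freq_tables = [freq_tables]
    path = Path(path)
    rows = ["locus\tallele\tcount\tfrequency"]
    for ft in freq_tables:
        total = sum(ft.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"locus {ft.locus}: frequencies sum to {total!r}, refusing to write"
            )
        for key in sorted(ft.counts, key=allele_label):
            rows.append(
                f"{ft.locus}\t{allele_label(key)}\t{ft.counts[key]}\t"
                f"{ft.frequencies[key]:.10g}"
            )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_frequency_table(path: Union[str, Path]) -> Dict[str, Dict[str, float]]:
    """Re-read a frequency TSV as ``{locus: {allele_label: frequency}}``."""
    out: Dict[str, Dict[str, float]] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        locus, label, _count, freq = line.split("\t")
        out.setdefault(locus, {})[label] = float(freq)
    return out


def dataset_summary(dataset: PopulationDataset) -> Dict[str, object]:
    """JSON-serializable overview: sizes, artifact counts, provenance."""
    pops = dataset.by_population()
    n_null = sum(1 for r in dataset.records if r.has_null())
    n_inter = sum(1 for r in dataset.records if r.has_intermediate())
    n_cnv = sum(1 for r in dataset.records if r.has_cnv)
    return {
        "n_samples": dataset.n,
        "n_loci": len(dataset.loci),
        "n_allele_columns": len(dataset.column_names()),
        "populations": {name: len(recs) for name, recs in pops.items()},
        "samples_with_null": n_null,
        "samples_with_intermediate": n_inter,
        "samples_with_cnv": n_cnv,
        "provenance": dict(dataset.provenance),
    }


def write_dataset_summary(dataset: PopulationDataset, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(dataset_summary(dataset), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
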