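"""Core data model for Y-STR haplotype panels.

A Y-STR allele is a repeat count, optionally with a fractional microvariant
step (``16.2`` = 16 full repeats plus 2 bases), or a null marker (``0``)
recording locus dropout.  A haplotype maps each panel locus to a tuple of
alleles: one value for single-copy loci, two for the duplicated DYS385a/b
locus (reported as an unordered, ascending-sorted pair).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np


class YstrError(Exception):
    """Base class for all ystrkit errors."""


class AlleleParseError(YstrError, ValueError):
    """Raised when an allele token cannot be interpreted."""


class ValidationError(YstrError, ValueError):
    """Raised when data violates a panel or dataset invariant."""


_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")

#: microvariant steps observed in forensic Y-STR reporting (tenths of a repeat)
VALID_STEPS = (0, 1, 2, 3)


@dataclass(frozen=True)
class Allele:
    """A single Y-STR allele: repeat count + microvariant step, or a null.

    Null alleles compare equal to each other regardless of the (meaningless)
    ``repeats``/``step`` they carry.
    """

    repeats: int = 0
    step: int = 0
    is_null: bool = False

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise ValidationError(f"negative repeat count: {self.repeats}")
        if self.step not in VALID_STEPS:
            raise ValidationError(f"microvariant step must be in {VALID_STEPS}: {self.step}")

    @property
    def value(self) -> float:
        """Numeric value on the repeat scale (e.g. 16.2); NaN for nulls."""
        if self.is_null:
            return float("nan")
        return self.repeats + self.step / 10.0

    @property
    def is_intermediate(self) -> bool:
        return (not self.is_null) and self.step != 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Allele):
            return NotImplemented
        if self.is_null or other.is_null:
            return self.is_null and other.is_null
        return self.repeats == other.repeats and self.step == other.step

    def __hash__(self) -> int:
        if self.is_null:
            return hash(("null",))
        return hash((self.repeats, self.step))

    def __lt__(self, other: "Allele") -> bool:
        # nulls sort first so sorted multi-copy tuples are deterministic
        return self._sort_key() < other._sort_key()

    def _sort_key(self) -> float:
        return -1.0 if self.is_null else self.value

    def __str__(self) -> str:
        if self.is_null:
            return "0"
        if self.step:
            return f"{self.repeats}.{self.step}"
        return str(self.repeats)


NULL_ALLELE = Allele(is_null=True)


def parse_allele(text: str) -> Allele:
    """Parse an allele token such as ``"16"``, ``"16.2"`` or ``"0"``.

    ``"0"`` denotes a null (locus deletion).  Dotted forms must carry a
    single-digit step in {1, 2, 3}.
    """
    token = text.strip()
    if not token:
        raise AlleleParseError("empty allele token")
    m = _ALLELE_RE.match(token)
    if m is None:
        raise AlleleParseError(f"malformed allele token: {token!r}")
    repeats = int(m.group(1))
    step = int(m.group(2)) if m.group(2) is not None else 0
    if m.group(2) is not None and step not in (1, 2, 3):
        raise AlleleParseError(f"microvariant step outside {{1,2,3}}: {token!r}")
    if repeats == 0 and step == 0:
        return NULL_ALLELE
    return Allele(repeats=repeats, step=step)


def format_allele(allele: Allele) -> str:
    return str(allele)


@dataclass(frozen=True)
class LocusDef:
    """One panel locus: name, expected copies per sample, DYS389 coupling."""

    name: str
    copy_number: int = 1
    needs_dys389_adjustment: bool = False


def _y23_panel() -> Tuple[LocusDef, ...]:
    single = [
        "DYS576", "DYS389I", "DYS448", "DYS389II", "DYS19", "DYS391",
        "DYS481", "DYS549", "DYS533", "DYS438", "DYS437", "DYS570",
        "DYS635", "DYS390", "DYS439", "DYS392", "DYS643", "DYS393",
        "DYS458", "DYS456", "YGATAH4",
    ]
    defs = [
        LocusDef(name, needs_dys389_adjustment=(name == "DYS389II"))
        for name in single
    ]
    defs.append(LocusDef("DYS385", copy_number=2))
    return tuple(defs)


#: PowerPlex Y23 panel: 21 single-copy loci plus the duplicated DYS385a/b,
#: i.e. 23 allele columns in all.
PANEL_Y23: Tuple[LocusDef, ...] = _y23_panel()

PANELS: Dict[str, Tuple[LocusDef, ...]] = {"y23": PANEL_Y23}


def get_panel(panel: "str | Sequence[LocusDef]") -> Tuple[LocusDef, ...]:
    if isinstance(panel, str):
        try:
            return PANELS[panel.lower()]
        except KeyError:
            raise ValidationError(f"unknown panel: {panel!r}") from None
    return tuple(panel)


Haplotype = Dict[str, Tuple[Allele, ...]]


@dataclass
class SampleRecord:
    """One male sample: ID, population label, full haplotype."""

    sample_id: str
    population: str
    haplotype: Haplotype
    cnv_loci: frozenset = frozenset()
    flags: Tuple[str, ...] = ()

    @property
    def has_cnv(self) -> bool:
        return bool(self.cnv_loci)

    def has_null(self) -> bool:
        return any(a.is_null for alleles in self.haplotype.values() for a in alleles)

    def has_intermediate(self) -> bool:
        return any(a.is_intermediate for alleles in self.haplotype.values() for a in alleles)


@dataclass
class PopulationDataset:
    """An ordered collection of sample records plus the locus registry."""

    records: List[SampleRecord]
    loci: Tuple[LocusDef, ...] = PANEL_Y23
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValidationError("dataset must contain at least one record")
        seen = set()
        for rec in self.records:
            if not rec.population:
                raise ValidationError(f"empty population label for sample {rec.sample_id!r}")
            if rec.sample_id in seen:
                raise ValidationError(f"duplicate sample ID: {rec.sample_id!r}")
            seen.add(rec.sample_id)

    @property
    def n(self) -> int:
        return len(self.records)

    def locus(self, name: str) -> LocusDef:
        for ld in self.loci:
            if ld.name == name:
                return ld
        raise ValidationError(f"locus not in panel: {name!r}")

    @property
    def locus_names(self) -> Tuple[str, ...]:
        return tuple(ld.name for ld in self.loci)

    def populations(self) -> Tuple[str, ...]:
        """Population labels in first-appearance order."""
        out: List[str] = []
        for rec in self.records:
            if rec.population not in out:
                out.append(rec.population)
        return tuple(out)

    def by_population(self) -> Dict[str, List[SampleRecord]]:
        groups: Dict[str, List[SampleRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.population, []).append(rec)
        return groups

    def subset(self, populations: Iterable[str]) -> "PopulationDataset":
        keep = set(populations)
        recs = [r for r in self.records if r.population in keep]
        return PopulationDataset(recs, self.loci, dict(self.provenance))

    def column_names(self, exclude_loci: Sequence[str] = ()) -> Tuple[str, ...]:
        """Allele column names, multi-copy loci expanded (DYS385 -> a, b)."""
        cols: List[str] = []
        excluded = set(exclude_loci)
        for ld in self.loci:
            if ld.name in excluded:
                continue
            if ld.copy_number == 1:
                cols.append(ld.name)
            else:
                cols.extend(f"{ld.name}{suffix}" for suffix in "ab"[: ld.copy_number])
        return tuple(cols)

    def to_repeat_matrix(
        self, exclude_loci: Sequence[str] = ()
    ) -> Tuple[np.ndarray, Tuple[str, ...]]:
        """Numeric (n_samples, n_columns) matrix of allele values.

        Requires a clean dataset: no nulls, no intermediates, no copy-number
        variants among the included loci (filter first, see
        :func:`ystrkit.amova.filter_for_rst`).
        """
        excluded = set(exclude_loci)
        cols = self.column_names(exclude_loci)
        mat = np.empty((self.n, len(cols)), dtype=float)
        for i, rec in enumerate(self.records):
            if rec.cnv_loci - excluded:
                raise ValidationError(
                    f"sample {rec.sample_id!r} carries a copy-number variant; filter first"
                )
            j = 0
            for ld in self.loci:
                if ld.name in excluded:
                    continue
                alleles = rec.haplotype[ld.name]
                for a in alleles[: ld.copy_number]:
                    if a.is_null or a.is_intermediate:
                        raise ValidationError(
                            f"sample {rec.sample_id!r} has a null/intermediate allele at "
                            f"{ld.name}; filter first"
                        )
                    mat[i, j] = a.value
                    j += 1
        return mat, cols

    def haplotype_key(
        self, rec: SampleRecord, loci_subset: Optional[Sequence[str]] = None
    ) -> Tuple[Tuple[str, ...], ...]:
        """Hashable haplotype identity (DYS385 sorted; nulls/microvariants kept)."""
        names = loci_subset if loci_subset is not None else self.locus_names
        return tuple(
            tuple(str(a) for a in sorted(rec.haplotype[name])) for name in names
        )


def make_haplotype(
    values: Dict[str, object], loci: Sequence[LocusDef] = PANEL_Y23
) -> Haplotype:
    """Convenience builder: ``{"DYS19": 14, "DYS385": (13, 17), ...}``.

    Values may be ints/floats, strings, :class:`Allele` instances, or tuples
    thereof for multi-copy loci.  Missing loci raise; multi-copy tuples are
    sorted ascending.
    """

    def to_allele(v: object) -> Allele:
        if isinstance(v, Allele):
            return v
        if isinstance(v, str):
            return parse_allele(v)
        if isinstance(v, int):
            return NULL_ALLELE if v == 0 else Allele(repeats=v)
        if isinstance(v, float):
            repeats = int(v)
            step = int(round((v - repeats) * 10))
            return NULL_ALLELE if v == 0 else Allele(repeats=repeats, step=step)
        raise ValidationError(f"cannot interpret allele value {v!r}")

    hap: Haplotype = {}
    for ld in loci:
        if ld.name not in values:
            raise ValidationError(f"haplotype missing locus {ld.name!r}")
        raw = values[ld.name]
        if isinstance(raw, (tuple, list)):
            alleles = tuple(sorted(to_allele(v) for v in raw))
        else:
            alleles = (to_allele(raw),)
        if len(alleles) < ld.copy_number:
            raise ValidationError(
                f"locus {ld.name!r} expects {ld.copy_number} alleles, got {len(alleles)}"
            )
        hap[ld.name] = alleles
    return hap
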