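"""Germplasm data model: accessions, S/M genotype labels, frequencies and concordance.

The central container is :class:`GermplasmTable`, a validated collection of
accessions each carrying an unordered S-allele pair, an unordered M-haplotype
pair, a self-(in)compatibility phenotype and a geographic group.  Readers
accept comma- or tab-delimited text with ``A/B`` genotype cells; ``?`` marks an
undefined haplotype.
"""

from __future__ import annotations

import csv
import io
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SSRMarker",
    "SAlleleLabel",
    "MHaplotypeLabel",
    "Accession",
    "GermplasmTable",
    "SelfPollinationRecord",
    "GermplasmError",
    "S_ALLELE_CATALOGUE",
    "GEOGRAPHIC_GROUPS",
    "PHENOTYPES",
    "read_germplasm_table",
    "write_germplasm_table",
    "read_selfing_table",
    "fruit_set_percentage",
    "allele_frequencies",
    "sc_concordance",
    "load_fixture_path",
]

#: All S-allele names admissible without the provisional flag.  S31 is the
#: label used in the germplasm table for the allele the sequence analysis
#: suggests is S22; both are kept in the catalogue.
S_ALLELE_CATALOGUE = frozenset(
    {f"S{i}" for i in range(1, 25)} | {"S31", "SC", "SV", "SX", "SZ"}
)

GEOGRAPHIC_GROUPS = frozenset({"WE", "EE", "NA", "SE/NAf", "unknown"})
PHENOTYPES = frozenset({"SI", "SC", "male-sterile", "undetermined"})

_MHAP_RE = re.compile(r"^(m|M)(\d+)(?:-(\d+))?$")


class GermplasmError(ValueError):
    """Raised for malformed or catalogue-violating germplasm input."""


@dataclass(frozen=True)
class SSRMarker:
    """A microsatellite marker with its repeat unit length in bp."""

    name: str
    repeat_motif_length: int = 2
    genomic_anchor: str | None = None

    def __post_init__(self) -> None:
        if self.repeat_motif_length < 1:
            raise GermplasmError(
                f"marker {self.name!r}: repeat_motif_length must be >= 1"
            )


@dataclass(frozen=True)
class SAlleleLabel:
    """An S-allele name, checked against the catalogue unless provisional."""

    name: str
    provisional: bool = False

    def __post_init__(self) -> None:
        if not self.provisional and self.name not in S_ALLELE_CATALOGUE:
            raise GermplasmError(
                f"S-allele {self.name!r} is not in the catalogue; "
                "pass provisional=True to admit it"
            )

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name


@dataclass(frozen=True)
class MHaplotypeLabel:
    """An M-haplotype label: main class plus optional subtype.

    The pollen-part mutated class is the distinguished lower-case ``m0``;
    every other class renders as ``M<k>``.  ``unknown`` labels render as
    the reserved token ``?``.
    """

    main_class: str  # "m0", "M1", ..., or "?" for unknown
    subtype: int | None = None

    @classmethod
    def parse(cls, text: str) -> "MHaplotypeLabel":
        text = text.strip()
        if text in {"?", "M?", "unknown"}:
            return cls("?", None)
        m = _MHAP_RE.match(text)
        if not m:
            raise GermplasmError(f"cannot parse M-haplotype label {text!r}")
        prefix, cls_idx, sub = m.groups()
        main = f"{prefix}{int(cls_idx)}"
        if prefix == "m" and int(cls_idx) != 0:
            raise GermplasmError(
                f"lower-case class is reserved for m0, got {text!r}"
            )
        return cls(main, None if sub is None else int(sub))

    @property
    def is_unknown(self) -> bool:
        return self.main_class == "?"

    def __str__(self) -> str:
        if self.is_unknown:
            return "?"
        if self.subtype is None:
            return self.main_class
        return f"{self.main_class}-{self.subtype}"


@dataclass(frozen=True)
class Accession:
    id: str
    name: str
    geographic_group: str
    phenotype: str
    s_genotype: frozenset | tuple  # pair of SAlleleLabel (tuple keeps homozygotes)
    m_genotype: tuple  # pair of MHaplotypeLabel
    clonal_parent: str | None = None

    def __post_init__(self) -> None:
        if self.geographic_group not in GEOGRAPHIC_GROUPS:
            raise GermplasmError(
                f"accession {self.id}: unknown geographic group "
                f"{self.geographic_group!r}"
            )
        if self.phenotype not in PHENOTYPES:
            raise GermplasmError(
                f"accession {self.id}: unknown phenotype {self.phenotype!r}"
            )
        if len(self.s_genotype) != 2 or len(self.m_genotype) != 2:
            raise GermplasmError(
                f"accession {self.id}: genotypes must be allele pairs"
            )

    # Unordered-pair equality helpers -------------------------------------
    def s_alleles(self) -> tuple[str, str]:
        return tuple(sorted(a.name for a in self.s_genotype))

    def m_haplotypes(self) -> tuple[str, str]:
        return tuple(sorted(str(h) for h in self.m_genotype))

    def carries(self, s_allele: str | None = None, m_main_class: str | None = None) -> int:
        """Number of gene copies of the given S-allele and/or M main class."""
        n = 0
        if s_allele is not None:
            n += sum(1 for a in self.s_genotype if a.name == s_allele)
        if m_main_class is not None:
            n += sum(
                1 for h in self.m_genotype
                if not h.is_unknown and h.main_class == m_main_class
            )
        return n


@dataclass
class GermplasmTable:
    accessions: list[Accession]
    marker_panel: list[SSRMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.accessions]
        if len(ids) != len(set(ids)):
            dup = [k for k, v in Counter(ids).items() if v > 1]
            raise GermplasmError(f"duplicate accession ids: {dup}")
        names = {a.name for a in self.accessions}
        for a in self.accessions:
            if a.clonal_parent is not None and a.clonal_parent not in names:
                raise GermplasmError(
                    f"accession {a.id}: clonal_parent {a.clonal_parent!r} "
                    "names no accession in the table"
                )

    def __len__(self) -> int:
        return len(self.accessions)

    def __iter__(self):
        return iter(self.accessions)

    def get(self, name: str) -> Accession:
        for a in self.accessions:
            if a.name == name:
                return a
        raise KeyError(name)

    def without_clones(self) -> "GermplasmTable":
        """Drop accessions that are clonal selections of another accession."""
        return GermplasmTable(
            [a for a in self.accessions if a.clonal_parent is None],
            self.marker_panel,
        )


@dataclass(frozen=True)
class SelfPollinationRecord:
    accession: str
    bagged_flowers: int
    fruits_set: int
    progeny_n: int
    phenotype: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.fruits_set <= self.bagged_flowers):
            raise GermplasmError(
                f"{self.accession}: fruits_set must lie in [0, bagged_flowers]"
            )
        if self.progeny_n < 0:
            raise GermplasmError(f"{self.accession}: progeny_n must be >= 0")


def fruit_set_percentage(record: SelfPollinationRecord) -> float:
    """Fruit-setting percentage to one decimal, half-up as printed in trials."""
    from decimal import ROUND_HALF_UP, Decimal

    pct = Decimal(100 * record.fruits_set) / Decimal(record.bagged_flowers)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "id", "name", "geographic_group", "phenotype", "s_genotype", "m_genotype",
)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_pair(cell: str, line_no: int, what: str) -> tuple[str, str]:
    parts = cell.strip().split("/")
    if len(parts) != 2:
        raise GermplasmError(
            f"line {line_no}: {what} cell {cell!r} is not 'A/B' pair syntax"
        )
    return parts[0].strip(), parts[1].strip()


def read_germplasm_table(path: str | Path | io.TextIOBase) -> GermplasmTable:
    """Read a germplasm genotype/phenotype table from delimited text.

    The header must name ``id, name, geographic_group, phenotype, s_genotype,
    m_genotype``; ``clonal_parent`` is optional.  Genotype cells use ``A/B``
    syntax with ``?`` for undefined haplotypes.  Malformed rows raise
    :class:`GermplasmError` naming the offending line.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()
    lines = text.splitlines()
    if not lines:
        raise GermplasmError("empty germplasm file")
    delim = _sniff_delimiter(lines[0])
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    missing = [c for c in _REQUIRED_COLUMNS if c not in (reader.fieldnames or [])]
    if missing:
        raise GermplasmError(f"missing required column(s): {missing}")

    accessions: list[Accession] = []
    for line_no, row in enumerate(reader, start=2):
        sa, sb = _parse_pair(row["s_genotype"], line_no, "s_genotype")
        ma, mb = _parse_pair(row["m_genotype"], line_no, "m_genotype")
        try:
            s_pair = (SAlleleLabel(sa), SAlleleLabel(sb))
        except GermplasmError as exc:
            raise GermplasmError(f"line {line_no}: {exc}") from exc
        m_pair = (MHaplotypeLabel.parse(ma), MHaplotypeLabel.parse(mb))
        clonal = (row.get("clonal_parent") or "").strip() or None
        accessions.append(
            Accession(
                id=row["id"].strip(),
                name=row["name"].strip(),
                geographic_group=row["geographic_group"].strip(),
                phenotype=row["phenotype"].strip(),
                s_genotype=s_pair,
                m_genotype=m_pair,
                clonal_parent=clonal,
            )
        )
    return GermplasmTable(accessions)


def write_germplasm_table(table: GermplasmTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(_REQUIRED_COLUMNS) + ["clonal_parent"])
        for a in table:
            w.writerow([
                a.id, a.name, a.geographic_group, a.phenotype,
                f"{a.s_genotype[0]}/{a.s_genotype[1]}",
                f"{a.m_genotype[0]}/{a.m_genotype[1]}",
                a.clonal_parent or "",
            ])


def read_selfing_table(path: str | Path) -> list[SelfPollinationRecord]:
    """Read a self-pollination trial table (flowers bagged, fruits set, progeny)."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                SelfPollinationRecord(
                    accession=row["accession"],
                    bagged_flowers=int(row["bagged_flowers"]),
                    fruits_set=int(row["fruits_set"]),
                    progeny_n=int(row["progeny_n"]),
                    phenotype=row.get("phenotype") or None,
                )
            )
    return records


def load_fixture_path(name: str) -> Path:
    """Path of a packaged data file (germplasm, progeny and reference tables)."""
    ref = resources.files("apricot_gsi") / "data" / name
    with resources.as_file(ref) as p:
        return Path(p)


# ---------------------------------------------------------------------------
# Frequencies and concordance
# ---------------------------------------------------------------------------

@dataclass
class FrequencyResult:
    locus: str
    frequencies: dict[str, float]
    heterozygosity: float | None
    n_accessions: int
    n_excluded_unknown: int

    @property
    def has_data(self) -> bool:
        return bool(self.frequencies)


def allele_frequencies(
    table: GermplasmTable,
    locus: str = "S",
    *,
    exclude_clones: bool = False,
    by_main_class: bool = False,
) -> FrequencyResult:
    """Allele frequencies and Nei gene diversity H = 1 - sum(p_i^2) at a locus.

    ``locus`` is ``"S"`` or ``"M"``.  Accessions with an unknown genotype at
    the locus are excluded and counted.  With ``by_main_class`` the M-locus is
    tallied at main-class rather than subtype resolution.
    """
    if locus not in {"S", "M"}:
        raise GermplasmError(f"unknown locus {locus!r}")
    pool = table.without_clones() if exclude_clones else table
    counts: Counter[str] = Counter()
    n_used = 0
    n_excluded = 0
    for a in pool:
        if locus == "S":
            alleles = [x.name for x in a.s_genotype]
        else:
            if any(h.is_unknown for h in a.m_genotype):
                n_excluded += 1
                continue
            alleles = [
                h.main_class if by_main_class else str(h) for h in a.m_genotype
            ]
        counts.update(alleles)
        n_used += 1
    total = sum(counts.values())
    if total == 0:
        return FrequencyResult(locus, {}, None, 0, n_excluded)
    freqs = {k: v / total for k, v in sorted(counts.items())}
    h = 1.0 - sum(p * p for p in freqs.values())
    return FrequencyResult(locus, freqs, h, n_used, n_excluded)


@dataclass
class ConcordanceReport:
    """Cross-tabulation of phenotype against carried self-compatibility haplotypes."""

    carriage: dict[str, int]  # accession name -> copies of SC-conferring haplotypes (0-4)
    crosstab: dict[str, Counter]  # phenotype -> Counter(carriage count)
    sc_without_mutation: list[str]  # SC phenotype, no known SC haplotype
    si_with_mutation: list[str]  # SI phenotype, >=1 known SC haplotype


def sc_concordance(
    table: GermplasmTable,
    *,
    sc_allele: str = "SC",
    sc_m_class: str = "m0",
) -> ConcordanceReport:
    """Annotate each accession with its count of self-compatibility haplotypes.

    Counts gene copies (0-4) of the mutated S-allele plus the pollen-part
    mutated M main class, tabulates them against phenotype, and reports the
    two discordance lists: self-compatible accessions carrying no known
    mutation, and self-incompatible accessions carrying at least one.
    """
    carriage: dict[str, int] = {}
    crosstab: dict[str, Counter] = {p: Counter() for p in PHENOTYPES}
    list_i: list[str] = []
    list_ii: list[str] = []
    for a in table:
        n = a.carries(s_allele=sc_allele, m_main_class=sc_m_class)
        carriage[a.name] = n
        crosstab[a.phenotype][n] += 1
        if a.phenotype == "SC" and n == 0:
            list_i.append(a.name)
        elif a.phenotype == "SI" and n >= 1:
            list_ii.append(a.name)
    return ConcordanceReport(carriage, crosstab, list_i, list_ii)
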