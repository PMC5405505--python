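"""S-genotype calling from multi-assay PCR fragment-size signatures.

Each S-allele has a characteristic signature across a set of PCR assays:
fragment sizes for the first and second S-RNase introns and the 5'-UTR SFB
intron, plus a presence/absence assay for the 358-bp SFB insertion that
separates the mutated SC allele from its non-mutated ancestor S8.  Absence of
amplification is informative and is part of the signature.

Matching tolerances depend on how an assay is resolved: capillary
electrophoresis sizes match within +/-1 bp, agarose estimates within +/-10% of
the expected size, and the insertion assay is an exact boolean.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .germplasm import load_fixture_path

__all__ = [
    "Resolution",
    "Assay",
    "ASSAYS",
    "AlleleSizeReference",
    "FragmentProfile",
    "MatchWarning",
    "match_fragments",
    "GenotypeCall",
    "combine_assays",
    "call_profile",
    "DiscriminationResult",
    "discriminating_power",
    "load_reference",
]


class Resolution(str, Enum):
    CAPILLARY = "capillary-exact"
    AGAROSE = "agarose-approximate"
    PRESENCE = "presence/absence"


@dataclass(frozen=True)
class Assay:
    name: str
    resolution: Resolution


#: The assay panel: first-intron amplifications with two primer systems,
#: the agarose-sized second intron, the SFB 5'-UTR intron and the SFB
#: insertion presence assay.
ASSAYS: dict[str, Assay] = {
    "intron1_SR1": Assay("intron1_SR1", Resolution.CAPILLARY),
    "intron1_PruT2": Assay("intron1_PruT2", Resolution.CAPILLARY),
    "intron2_C2C6": Assay("intron2_C2C6", Resolution.AGAROSE),
    "sfb_5utr": Assay("sfb_5utr", Resolution.CAPILLARY),
    "sfb_insertion": Assay("sfb_insertion", Resolution.PRESENCE),
}

NO_AMP = None  # reference entry for "no amplification"


@dataclass
class AlleleSizeReference:
    """Expected per-assay signal for every catalogued allele.

    ``table[allele][assay]`` is a float size in bp, a bool for the insertion
    assay, or ``None`` for "no amplification".
    """

    table: dict[str, dict[str, float | bool | None]]

    @property
    def alleles(self) -> list[str]:
        return sorted(self.table)

    @property
    def assays(self) -> list[str]:
        first = next(iter(self.table.values()))
        return list(first)

    def expected(self, allele: str, assay: str):
        try:
            return self.table[allele][assay]
        except KeyError as exc:
            raise KeyError(f"allele {allele!r} / assay {assay!r} not in reference") from exc


def load_reference(path: str | Path | None = None) -> AlleleSizeReference:
    """Load an allele x assay reference from long-format CSV.

    Columns ``allele, assay, signal``; signal is a size in bp, ``none`` for
    no amplification, or 0/1 for the insertion assay.  Without a path the
    packaged reduced reference is used: a synthetic table reproducing the
    documented amplification and collision structure of the 20 catalogued
    alleles (exact supplementary sizes are not redistributed here; range
    anchors such as 260/427 bp for the first intron are kept).
    """
    if path is None:
        path = load_fixture_path("s_allele_reference_synthetic.csv")
    table: dict[str, dict[str, float | bool | None]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            allele, assay, signal = row["allele"], row["assay"], row["signal"].strip()
            if assay not in ASSAYS:
                raise ValueError(f"unknown assay {assay!r} in reference")
            if ASSAYS[assay].resolution is Resolution.PRESENCE:
                value: float | bool | None = bool(int(signal))
            elif signal.lower() in {"none", "na", ""}:
                value = NO_AMP
            else:
                value = float(signal)
            table.setdefault(allele, {})[assay] = value
    return AlleleSizeReference(table)


@dataclass
class FragmentProfile:
    """Measured fragment sizes for one diploid sample.

    ``sizes[assay]`` holds zero, one or two measured sizes in bp; an assay
    present with an empty list was attempted and showed no amplification.
    Assays absent from the dict were not attempted and are neutral.
    ``insertion_present`` is the boolean insertion-assay call (None if not
    attempted).
    """

    sample_id: str
    sizes: dict[str, list[float]] = field(default_factory=dict)
    insertion_present: bool | None = None

    def __post_init__(self) -> None:
        for assay, vals in self.sizes.items():
            if len(vals) > 2:
                raise ValueError(
                    f"{self.sample_id}/{assay}: at most two fragments per diploid sample"
                )


@dataclass(frozen=True)
class MatchWarning:
    sample_id: str
    assay: str
    size: float | None
    message: str


def _tolerance(assay: Assay, expected: float, capillary_bp: float) -> float:
    if assay.resolution is Resolution.CAPILLARY:
        return capillary_bp
    if assay.resolution is Resolution.AGAROSE:
        return 0.10 * expected
    return 0.0


def match_fragments(
    profile: FragmentProfile,
    reference: AlleleSizeReference,
    *,
    tolerance_capillary: float = 1.0,
) -> tuple[dict[str, dict[float | None, set[str]]], list[MatchWarning]]:
    """Per-assay candidate allele sets for each measured fragment.

    For every measured size the candidate set contains alleles whose expected
    size lies within the assay's tolerance window; an attempted assay with no
    product matches alleles annotated "no amplification".  A size matching
    nothing yields an empty set and a warning record (possible new allele).
    """
    candidates: dict[str, dict[float | None, set[str]]] = {}
    warnings: list[MatchWarning] = []
    for assay_name, observed in profile.sizes.items():
        assay = ASSAYS[assay_name]
        per_assay: dict[float | None, set[str]] = {}
        if not observed:
            per_assay[None] = {
                a for a in reference.alleles
                if reference.expected(a, assay_name) is NO_AMP
            }
        for size in observed:
            hits = set()
            for allele in reference.alleles:
                exp = reference.expected(allele, assay_name)
                if exp is NO_AMP or isinstance(exp, bool):
                    continue
                if abs(size - exp) <= _tolerance(assay, exp, tolerance_capillary):
                    hits.add(allele)
            if not hits:
                warnings.append(
                    MatchWarning(
                        profile.sample_id, assay_name, size,
                        f"size {size} bp matches no catalogued allele "
                        "(possible new allele)",
                    )
                )
            per_assay[size] = hits
        candidates[assay_name] = per_assay
    return candidates, warnings


@dataclass
class GenotypeCall:
    sample_id: str
    alleles: tuple[str, str] | None  # resolved unordered pair, or None
    ambiguous_pairs: list[tuple[str, str]] = field(default_factory=list)
    resolving_assays: dict[str, str] = field(default_factory=dict)
    conflict: bool = False
    conflicting_assays: list[str] = field(default_factory=list)
    warnings: list[MatchWarning] = field(default_factory=list)

    @property
    def resolved(self) -> bool:
        return self.alleles is not None and not self.ambiguous_pairs


def _pair_explains_assay(
    pair: tuple[str, str],
    assay_name: str,
    observed: list[float],
    reference: AlleleSizeReference,
    tolerance_capillary: float,
) -> bool:
    """Does the allele pair predict exactly the observed fragment pattern?"""
    assay = ASSAYS[assay_name]
    expected = [reference.expected(a, assay_name) for a in pair]
    expected_sizes = [e for e in expected if e is not NO_AMP]
    # collapse indistinguishable expectations (homozygote or shared size)
    merged: list[float] = []
    for e in expected_sizes:
        if not any(abs(e - m) <= _tolerance(assay, m, tolerance_capillary) for m in merged):
            merged.append(e)
    if len(merged) != len(observed):
        return False
    # each observed size must match one merged expected size and vice versa
    unmatched = list(merged)
    for size in observed:
        hit = next(
            (m for m in unmatched
             if abs(size - m) <= _tolerance(assay, m, tolerance_capillary)),
            None,
        )
        if hit is None:
            return False
        unmatched.remove(hit)
    return not unmatched


def _pair_explains_insertion(
    pair: tuple[str, str], present: bool, reference: AlleleSizeReference
) -> bool:
    expected_any = any(bool(reference.expected(a, "sfb_insertion")) for a in pair)
    return expected_any == present


def combine_assays(
    profile: FragmentProfile,
    reference: AlleleSizeReference,
    *,
    tolerance_capillary: float = 1.0,
) -> GenotypeCall:
    """Combine per-assay evidence into a diploid S-genotype call.

    All unordered allele pairs consistent with every attempted assay are
    enumerated.  A single surviving pair is a resolved call; several pairs
    yield an ambiguity list plus, per unattempted assay, whether it would
    discriminate the candidates (e.g. the insertion assay for {SC, S8}); no
    surviving pair with amplifying assays is flagged as a conflict naming the
    assays that disagree.
    """
    _, warnings = match_fragments(
        profile, reference, tolerance_capillary=tolerance_capillary
    )
    alleles = reference.alleles
    pairs = [
        tuple(sorted(p))
        for p in itertools.combinations_with_replacement(alleles, 2)
    ]
    surviving = []
    for pair in pairs:
        ok = all(
            _pair_explains_assay(pair, name, obs, reference, tolerance_capillary)
            for name, obs in profile.sizes.items()
        )
        if ok and profile.insertion_present is not None:
            ok = _pair_explains_insertion(pair, profile.insertion_present, reference)
        if ok:
            surviving.append(pair)

    if not surviving:
        attempted = [n for n, v in profile.sizes.items() if v]
        return GenotypeCall(
            profile.sample_id, None, conflict=True,
            conflicting_assays=attempted, warnings=warnings,
        )
    if len(surviving) == 1:
        return GenotypeCall(profile.sample_id, surviving[0], warnings=warnings)

    # ambiguous: report candidates and the minimal extra assay resolving them
    resolving: dict[str, str] = {}
    attempted = set(profile.sizes)
    if profile.insertion_present is not None:
        attempted.add("sfb_insertion")
    for assay_name in ASSAYS:
        if assay_name in attempted:
            continue
        signatures = set()
        for pair in surviving:
            sig = tuple(sorted(
                (repr(reference.expected(a, assay_name)) for a in pair)
            ))
            signatures.add(sig)
        if len(signatures) == len(surviving):
            resolving[assay_name] = "discriminates all candidate pairs"
    return GenotypeCall(
        profile.sample_id, surviving[0], ambiguous_pairs=surviving,
        resolving_assays=resolving, warnings=warnings,
    )


def call_profile(
    profile: FragmentProfile,
    reference: AlleleSizeReference,
    *,
    tolerance_capillary: float = 1.0,
) -> GenotypeCall:
    """Convenience wrapper: match then combine."""
    return combine_assays(
        profile, reference, tolerance_capillary=tolerance_capillary
    )


@dataclass
class DiscriminationResult:
    """Discriminating power of an assay subset over the catalogued alleles.

    ``n_signatures`` counts distinct observable signature classes among
    alleles that amplify in at least one chosen assay (the per-assay
    "number of alleles distinguished" figure); ``n_unique`` counts alleles
    whose combined signature is globally unique (unambiguously resolvable).
    """

    assays: tuple[str, ...]
    n_signatures: int
    n_unique: int
    unresolved_groups: list[frozenset[str]]
    non_amplifying: frozenset[str]


def discriminating_power(
    reference: AlleleSizeReference,
    assays: Sequence[str] | None = None,
) -> DiscriminationResult:
    """Group alleles by their expected signature over an assay subset."""
    chosen = tuple(assays) if assays is not None else tuple(ASSAYS)
    for a in chosen:
        if a not in ASSAYS:
            raise ValueError(f"unknown assay {a!r}")
    groups: dict[tuple, set[str]] = {}
    non_amp = set()
    for allele in reference.alleles:
        sig = tuple(reference.expected(allele, a) for a in chosen)
        if all(
            s is NO_AMP or (isinstance(s, bool) and not s) for s in sig
        ):
            non_amp.add(allele)
        groups.setdefault(sig, set()).add(allele)
    amplifying_sigs = {
        sig for sig in groups
        if not all(s is NO_AMP or (isinstance(s, bool) and not s) for s in sig)
    }
    unresolved = sorted(
        (frozenset(v) for v in groups.values() if len(v) > 1),
        key=lambda g: sorted(g),
    )
    n_unique = sum(1 for v in groups.values() if len(v) == 1)
    if not chosen:
        return DiscriminationResult((), 0, 0, [frozenset(reference.alleles)],
                                    frozenset(reference.alleles))
    return DiscriminationResult(
        chosen, len(amplifying_sigs), n_unique, unresolved, frozenset(non_amp)
    )
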