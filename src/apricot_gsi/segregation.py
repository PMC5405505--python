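"""Selfing-progeny segregation tests and localisation of SC mutations.

Under gametophytic self-incompatibility only pollen that escapes S-RNase
rejection fertilises.  Selfing a heterozygote S_a/S_b whose self-compatibility
comes from a mutation *linked* to one S-haplotype (a pollen-part mutation in
that haplotype's SFB, as in SC) transmits only the mutated pollen class, so
progeny segregate 1:1 {heterozygote : mutated homozygote} with the other
homozygote class absent.  If instead the mutation is *unlinked* to the
S-locus (a modifier such as the m0 M-haplotype) all pollen transmits and the
S-locus segregates 1:2:1.  An SSR tightly linked to the modifier corroborates
the unlinked case: only pollen carrying the mutated modifier haplotype
transmits at that locus, giving 1:1 with the repulsion-phase homozygote
absent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

from scipy import stats

from .germplasm import GermplasmError, load_fixture_path

__all__ = [
    "SegregationRecord",
    "RatioTestResult",
    "chisq_ratio",
    "MutationLocation",
    "Classification",
    "classify_mutation_location",
    "TransmissionModel",
    "expected_selfing_ratios",
    "read_progeny_table",
]


@dataclass(frozen=True)
class SegregationRecord:
    """Progeny S-genotype class counts from one controlled self-pollination.

    ``counts`` are (hom-A, het, hom-B) for parent genotype A/B.  Optional
    ``marker_counts`` are the two M-linked SSR progeny classes
    (het, coupling-homozygote) with the repulsion homozygote count third.
    """

    parent: str
    allele_a: str
    allele_b: str
    counts: tuple[int, int, int]
    n_total: int | None = None
    n_analyzed: int | None = None
    marker: str | None = None
    marker_counts: tuple[int, int, int] | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise GermplasmError(f"{self.parent}: negative class count")
        if self.n_analyzed is not None and sum(self.counts) != self.n_analyzed:
            raise GermplasmError(
                f"{self.parent}: class counts sum to {sum(self.counts)}, "
                f"not n_analyzed={self.n_analyzed}"
            )


@dataclass(frozen=True)
class RatioTestResult:
    chi2: float
    df: int
    p: float
    ratio: tuple[int, ...]

    def __post_init__(self) -> None:
        assert self.chi2 >= 0 and 0.0 <= self.p <= 1.0


def chisq_ratio(counts: Sequence[int], ratio: Sequence[int]) -> RatioTestResult:
    """Pearson goodness-of-fit of observed counts to an expected integer ratio.

    No continuity correction; df = classes - 1.  All ratio terms must be
    positive so expected counts are never zero.
    """
    if len(counts) != len(ratio):
        raise GermplasmError("counts and ratio must have the same length")
    if len(counts) < 2:
        raise GermplasmError("need at least two classes")
    if any(r <= 0 for r in ratio):
        raise GermplasmError("ratio terms must be positive")
    total = sum(counts)
    if total <= 0:
        raise GermplasmError("total count must be positive")
    rsum = sum(ratio)
    expected = [total * r / rsum for r in ratio]
    chi2, p = stats.chisquare(list(counts), expected)
    return RatioTestResult(float(chi2), len(counts) - 1, float(p), tuple(ratio))


class MutationLocation(str, Enum):
    S_LINKED = "S-linked PPM"
    S_UNLINKED = "S-unlinked PPM"
    M_LINKED = "S-unlinked PPM (M-linked)"
    UNDETERMINED = "undetermined"


@dataclass
class Classification:
    location: MutationLocation
    s_linked_test: RatioTestResult | None
    unlinked_test: RatioTestResult | None
    marker_test: RatioTestResult | None = None
    mutated_allele: str | None = None
    excess_homozygote_flag: str | None = None
    reason: str = ""


def classify_mutation_location(
    record: SegregationRecord,
    *,
    alpha: float = 0.05,
    min_n: int = 10,
) -> Classification:
    """Decide whether the SC mutation is S-linked or S-unlinked (M-linked).

    The S-linked model predicts the non-mutated homozygote class to be
    structurally absent and 1:1 {het : mutated homozygote}; any count in that
    class disfavours the pure S-linked model outright.  The unlinked model
    predicts 1:2:1 over all three classes.  Classification requires one model
    retained at ``alpha`` and the other rejected (or excluded by the absent
    class); marker counts, when present, corroborate M-linkage via a 1:1 test
    with the repulsion-phase homozygote expected absent.  Fewer than
    ``min_n`` analysed progeny is an insufficient-data floor.
    """
    if record.allele_a == record.allele_b:
        return Classification(
            MutationLocation.UNDETERMINED, None, None,
            reason="parent homozygous at S",
        )
    hom_a, het, hom_b = record.counts
    n = sum(record.counts)
    if n < min_n:
        return Classification(
            MutationLocation.UNDETERMINED, None, None,
            reason=f"insufficient data (n={n} < {min_n})",
        )

    # S-linked candidate orientations: the absent homozygote marks the
    # non-mutated allele; its observed presence rejects that orientation.
    s_linked_result = None
    mutated = None
    for mut_allele, hom_mut, hom_other in (
        (record.allele_b, hom_b, hom_a),
        (record.allele_a, hom_a, hom_b),
    ):
        if hom_other == 0:
            res = chisq_ratio((het, hom_mut), (1, 1))
            if s_linked_result is None or res.p > s_linked_result.p:
                s_linked_result = res
                mutated = mut_allele
    s_linked_ok = s_linked_result is not None and s_linked_result.p >= alpha

    unlinked_result = chisq_ratio(record.counts, (1, 2, 1))
    unlinked_ok = unlinked_result.p >= alpha

    # An over-represented homozygote class under the unlinked model hints at
    # a second mutation affecting that allele.
    excess = None
    exp_hom = n / 4
    if hom_a > 2 * exp_hom:
        excess = record.allele_a
    elif hom_b > 2 * exp_hom:
        excess = record.allele_b

    marker_result = None
    if record.marker_counts is not None:
        m_het, m_hom_coupling, m_hom_repulsion = record.marker_counts
        if m_hom_repulsion == 0:
            marker_result = chisq_ratio((m_het, m_hom_coupling), (1, 1))

    if s_linked_ok and not unlinked_ok:
        return Classification(
            MutationLocation.S_LINKED, s_linked_result, unlinked_result,
            marker_result, mutated_allele=mutated,
            excess_homozygote_flag=excess,
            reason="1:1 retained, 1:2:1 rejected, non-mutated homozygote absent",
        )
    if unlinked_ok and not s_linked_ok:
        location = MutationLocation.S_UNLINKED
        reason = "1:2:1 retained, both homozygote classes populated"
        if marker_result is not None and marker_result.p >= alpha:
            location = MutationLocation.M_LINKED
            reason += ("; M-linked SSR 1:1 retained with repulsion "
                       "homozygote absent")
        return Classification(
            location, s_linked_result, unlinked_result, marker_result,
            excess_homozygote_flag=excess, reason=reason,
        )
    return Classification(
        MutationLocation.UNDETERMINED, s_linked_result, unlinked_result,
        marker_result, excess_homozygote_flag=excess,
        reason="models not separable (both retained or both rejected)",
    )


# ---------------------------------------------------------------------------
# Expected selfing ratios under a transmission model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransmissionModel:
    """Which haplotypes let pollen escape S-RNase rejection.

    ``s_compatible_pollen`` are S-haplotype labels with a pollen-part
    mutation in their own SFB (e.g. {"SC"}); ``m_ppm_haplotypes`` are
    M-locus main classes whose pollen-part mutation disables rejection
    regardless of the pollen's S-haplotype (e.g. {"m0"}).  Ovule
    transmission is always Mendelian (pollen-part action only), and the S-
    and M-loci assort independently.
    """

    s_compatible_pollen: frozenset[str] = frozenset()
    m_ppm_haplotypes: frozenset[str] = frozenset()


@dataclass
class SelfingExpectation:
    s_genotype_probs: dict[tuple[str, str], float]
    m_genotype_probs: dict[tuple[str, str], float]
    compatible_pollen_fraction: float

    @property
    def no_progeny(self) -> bool:
        return self.compatible_pollen_fraction == 0.0


def expected_selfing_ratios(
    s_genotype: tuple[str, str],
    m_genotype: tuple[str, str],
    model: TransmissionModel,
) -> SelfingExpectation:
    """Closed-form progeny genotype proportions for a selfed parent.

    Pollen gametes (s, m) are uniform over the four parental combinations and
    accepted iff the S-haplotype is pollen-part mutated or the M-haplotype
    carries the modifier PPM; ovule gametes are unconditionally Mendelian.
    The S- and M-marginals are computed from the joint conditional pollen
    distribution, so linkage of acceptance across the two loci is respected.
    """
    s_alleles = tuple(s_genotype)
    m_haps = tuple(m_genotype)
    pollen = [
        (s, m) for s in s_alleles for m in m_haps
    ]
    accepted = [
        (s, m) for (s, m) in pollen
        if s in model.s_compatible_pollen or m in model.m_ppm_haplotypes
    ]
    frac = len(accepted) / len(pollen)
    if not accepted:
        return SelfingExpectation({}, {}, 0.0)

    s_probs: dict[tuple[str, str], float] = {}
    m_probs: dict[tuple[str, str], float] = {}
    w_pollen = 1.0 / len(accepted)
    w_ovule = 1.0 / 2.0
    for ps, pm in accepted:
        for ovule_s in s_alleles:
            key = tuple(sorted((ovule_s, ps)))
            s_probs[key] = s_probs.get(key, 0.0) + w_pollen * w_ovule
        for ovule_m in m_haps:
            key = tuple(sorted((ovule_m, pm)))
            m_probs[key] = m_probs.get(key, 0.0) + w_pollen * w_ovule
    assert abs(sum(s_probs.values()) - 1.0) < 1e-12
    assert abs(sum(m_probs.values()) - 1.0) < 1e-12
    return SelfingExpectation(s_probs, m_probs, frac)


def read_progeny_table(path: str | Path | None = None) -> list[SegregationRecord]:
    """Read selfing progeny S-genotype class counts (packaged table by default)."""
    if path is None:
        path = load_fixture_path("table4_progeny.csv")
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                SegregationRecord(
                    parent=row["parent"],
                    allele_a=row["allele_a"],
                    allele_b=row["allele_b"],
                    counts=(
                        int(row["n_hom_a"]), int(row["n_het"]), int(row["n_hom_b"])
                    ),
                    n_total=int(row["n_total"]) if row.get("n_total") else None,
                    n_analyzed=(
                        int(row["n_analyzed"]) if row.get("n_analyzed") else None
                    ),
                    marker=row.get("m_marker") or None,
                    note=row.get("note") or None,
                )
            )
    return records
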