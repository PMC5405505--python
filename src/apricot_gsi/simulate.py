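"""Synthetic-data generators for the GSI genetic model.

Three generators cover the experimental designs the analysis modules expect:
selfing progenies under gametophytic pollen rejection with pollen-part
mutations (S-linked or modifier-linked), diploid germplasm panels with SSR
haplotypes diverged by stepwise mutation, and multi-assay fragment profiles
with bounded integer size noise.  Every stochastic operation takes an
explicit seed and is byte-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .germplasm import GermplasmError, SSRMarker
from .m_haplotypes import MHaplotype, SSRGenotypeMatrix
from .s_alleles import ASSAYS, NO_AMP, AlleleSizeReference, FragmentProfile, Resolution
from .segregation import SegregationRecord, TransmissionModel, expected_selfing_ratios

__all__ = [
    "TransmissionModel",
    "PanelSimConfig",
    "SelfingSimResult",
    "simulate_selfing_progeny",
    "PanelSimResult",
    "simulate_germplasm_panel",
    "simulate_fragment_profiles",
]


@dataclass
class SelfingSimResult:
    progeny_s: list[tuple[str, str]]
    progeny_m: list[tuple[str, str]]
    record: SegregationRecord | None
    no_progeny: bool
    seed: int


def simulate_selfing_progeny(
    s_genotype: tuple[str, str],
    m_genotype: tuple[str, str],
    model: TransmissionModel,
    n: int,
    seed: int,
) -> SelfingSimResult:
    """Simulate ``n`` selfed progeny under absolute pollen rejection.

    Each progeny pairs a Mendelian ovule gamete with a pollen gamete drawn
    from the compatible pollen classes (rejection is absolute, so conditional
    sampling over accepted gametes is exact).  S and M assort independently
    within a gamete; acceptance couples them.  Returns the genotype lists and
    the aggregated :class:`SegregationRecord` (class order: hom-A, het,
    hom-B for the parent's A/B genotype).
    """
    if n < 0:
        raise GermplasmError("n must be >= 0")
    expectation = expected_selfing_ratios(s_genotype, m_genotype, model)
    if expectation.no_progeny:
        return SelfingSimResult([], [], None, n > 0, seed)

    rng = np.random.default_rng(seed)
    s_alleles = tuple(s_genotype)
    m_haps = tuple(m_genotype)
    pollen_classes = [
        (s, m) for s in s_alleles for m in m_haps
        if s in model.s_compatible_pollen or m in model.m_ppm_haplotypes
    ]
    progeny_s: list[tuple[str, str]] = []
    progeny_m: list[tuple[str, str]] = []
    pollen_idx = rng.integers(0, len(pollen_classes), size=n)
    ovule_s_idx = rng.integers(0, 2, size=n)
    ovule_m_idx = rng.integers(0, 2, size=n)
    for k in range(n):
        ps, pm = pollen_classes[pollen_idx[k]]
        progeny_s.append(tuple(sorted((s_alleles[ovule_s_idx[k]], ps))))
        progeny_m.append(tuple(sorted((m_haps[ovule_m_idx[k]], pm))))

    a, b = s_genotype
    hom_a = sum(1 for g in progeny_s if g == (a, a))
    hom_b = sum(1 for g in progeny_s if g == (b, b))
    het = n - hom_a - hom_b if a != b else 0
    record = SegregationRecord(
        parent="simulated", allele_a=a, allele_b=b,
        counts=(hom_a, het, hom_b) if a != b else (n, 0, 0),
        n_total=n, n_analyzed=n,
    )
    return SelfingSimResult(progeny_s, progeny_m, record, False, seed)


# ---------------------------------------------------------------------------
# Germplasm panel simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSimConfig:
    """Study conditions for a synthetic SSR haplotype panel.

    Defaults mirror the scale of the real germplasm survey: a handful of
    deeply diverged ancestral haplotypes (main classes), descendants within a
    few stepwise mutations of their ancestor, seven dinucleotide markers, and
    a low rate of missing genotype calls.
    """

    n_ancestors: int = 4
    n_descendants_per_ancestor: int = 3
    n_accessions: int = 50
    stepwise_mutation_steps: float = 1.0  # mean of the geometric step draw
    max_steps_per_descendant: int = 3
    ancestor_separation_repeats: int = 6
    genotyping_missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.genotyping_missing_rate <= 1.0):
            raise GermplasmError("missing rate must lie in [0, 1]")
        if self.n_ancestors < 1:
            raise GermplasmError("need at least one ancestor")


@dataclass
class PanelSimResult:
    haplotypes: list[MHaplotype]  # truth, labelled A<i>.D<j>
    ancestor_of: dict[str, int]  # haplotype label -> ancestor index
    matrix: SSRGenotypeMatrix  # observed diploid genotypes with missingness
    true_pairs: dict[str, tuple[str, str]]  # accession -> haplotype labels
    panel: list[SSRMarker]
    seed: int


def simulate_germplasm_panel(config: PanelSimConfig) -> PanelSimResult:
    """Ancestral haplotypes, stepwise-mutated descendants, diploid genotypes.

    Ancestors are placed ``ancestor_separation_repeats`` repeat units apart at
    every locus, descendants mutate at most ``max_steps_per_descendant``
    single-repeat steps (geometric step counts, symmetric direction) spread
    over distinct loci, and accessions pair haplotypes uniformly at random.
    The full truth is returned alongside the observed matrix.
    """
    rng = np.random.default_rng(config.seed)
    panel = [
        SSRMarker(f"SSR{i+1}", 2, None) for i in range(7)
    ]
    n_loci = len(panel)
    sep = config.ancestor_separation_repeats

    haplotypes: list[MHaplotype] = []
    ancestor_of: dict[str, int] = {}
    for ai in range(config.n_ancestors):
        base = tuple(
            100.0 + 20 * li + panel[li].repeat_motif_length * sep * ai
            for li in range(n_loci)
        )
        label = f"A{ai}.D0"
        haplotypes.append(MHaplotype(label, base))
        ancestor_of[label] = ai
        for di in range(1, config.n_descendants_per_ancestor + 1):
            alleles = list(base)
            if config.max_steps_per_descendant > 0 and config.stepwise_mutation_steps > 0:
                p = 1.0 / (1.0 + config.stepwise_mutation_steps)
                n_steps = min(
                    int(rng.geometric(p) - 1), config.max_steps_per_descendant
                )
                loci = rng.choice(n_loci, size=n_steps, replace=False)
                for li in loci:
                    step = panel[li].repeat_motif_length * (
                        1 if rng.random() < 0.5 else -1
                    )
                    alleles[li] += step
            label = f"A{ai}.D{di}"
            haplotypes.append(MHaplotype(label, tuple(alleles)))
            ancestor_of[label] = ai

    labels = [h.label for h in haplotypes]
    by_label = {h.label: h for h in haplotypes}
    genotypes: dict[str, list[tuple[float, float] | None]] = {}
    true_pairs: dict[str, tuple[str, str]] = {}
    for k in range(config.n_accessions):
        l1, l2 = rng.choice(labels, size=2, replace=True)
        true_pairs[f"acc{k}"] = (l1, l2)
        row: list[tuple[float, float] | None] = []
        for li in range(n_loci):
            if rng.random() < config.genotyping_missing_rate:
                row.append(None)
            else:
                row.append((by_label[l1].alleles[li], by_label[l2].alleles[li]))
        genotypes[f"acc{k}"] = row
    matrix = SSRGenotypeMatrix([m.name for m in panel], genotypes)
    return PanelSimResult(haplotypes, ancestor_of, matrix, true_pairs, panel, config.seed)


# ---------------------------------------------------------------------------
# Fragment profile simulation
# ---------------------------------------------------------------------------

def simulate_fragment_profiles(
    s_genotypes: Sequence[tuple[str, str]],
    reference: AlleleSizeReference,
    *,
    size_noise_bp: int = 0,
    seed: int = 0,
    assays: Sequence[str] | None = None,
) -> list[FragmentProfile]:
    """Expected multi-assay profiles with bounded integer size noise.

    Every genotype's expected fragment set is emitted per assay, each size
    perturbed by a uniform integer offset in [-size_noise_bp, size_noise_bp];
    the insertion assay is emitted noiselessly.  Alleles absent from the
    reference raise an error.
    """
    rng = np.random.default_rng(seed)
    chosen = list(assays) if assays is not None else list(ASSAYS)
    profiles = []
    for idx, pair in enumerate(s_genotypes):
        for allele in pair:
            if allele not in reference.table:
                raise GermplasmError(f"allele {allele!r} absent from reference")
        sizes: dict[str, list[float]] = {}
        insertion: bool | None = None
        for assay_name in chosen:
            if ASSAYS[assay_name].resolution is Resolution.PRESENCE:
                insertion = any(
                    bool(reference.expected(a, assay_name)) for a in pair
                )
                continue
            observed: list[float] = []
            for exp in {reference.expected(a, assay_name) for a in pair}:
                if exp is NO_AMP:
                    continue
                noise = (
                    int(rng.integers(-size_noise_bp, size_noise_bp + 1))
                    if size_noise_bp > 0 else 0
                )
                observed.append(float(exp) + noise)
            sizes[assay_name] = sorted(observed)
        profiles.append(
            FragmentProfile(f"sim{idx}", sizes, insertion_present=insertion)
        )
    return profiles
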