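"""M-locus SSR haplotypes: linkage phasing, EM frequency inference, main classes.

The M-locus is a block of seven tightly linked SSR markers at the distal end
of chromosome 3.  Within the block recombination is treated as negligible, so
a haplotype is simply an ordered vector of seven allele sizes.  Diploid SSR
genotypes (unordered size pairs per marker) are phased either directly from
selfing/cross progenies (co-transmission maximisation) or statistically with
an expectation-maximisation estimate of population haplotype frequencies.
Inferred haplotypes are grouped into "main classes": connected components of
the graph that joins haplotypes differing at no more than ``max_diff`` loci.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .germplasm import GermplasmError, MHaplotypeLabel, SSRMarker, load_fixture_path

__all__ = [
    "MHaplotype",
    "SSRGenotypeMatrix",
    "PhaseResult",
    "phase_from_progeny",
    "HaplotypeFrequencyEstimate",
    "em_haplotype_inference",
    "MainClassAssignment",
    "assign_main_classes",
    "load_reference_haplotypes",
    "load_marker_panel",
]

Alleles = tuple  # tuple of float|None, one per marker


@dataclass(frozen=True)
class MHaplotype:
    """An M-locus haplotype: a label plus ordered SSR allele sizes in bp."""

    label: str
    alleles: Alleles  # length == panel size; None marks a missing call

    def __post_init__(self) -> None:
        if any(a is not None and a <= 0 for a in self.alleles):
            raise GermplasmError(f"haplotype {self.label}: sizes must be positive")

    def n_missing(self) -> int:
        return sum(1 for a in self.alleles if a is None)

    def differences(self, other: "MHaplotype") -> int:
        """Number of loci, observed in both, at which the alleles differ."""
        return sum(
            1 for a, b in zip(self.alleles, other.alleles)
            if a is not None and b is not None and a != b
        )


def load_marker_panel(path: str | Path | None = None) -> list[SSRMarker]:
    """The seven M-locus SSR markers (packaged descriptor table by default)."""
    if path is None:
        path = load_fixture_path("ssr_markers_synthetic.csv")
    panel = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            panel.append(
                SSRMarker(
                    row["name"], int(row["repeat_motif_length"]),
                    row.get("genomic_anchor") or None,
                )
            )
    return panel


def load_reference_haplotypes(path: str | Path | None = None) -> list[MHaplotype]:
    """Load a haplotype x SSR allele-size table.

    The packaged default is a synthetic stand-in reproducing the structural
    relations of the published haplotype set: 38 haplotypes whose labels span
    20 main classes, with subtypes differing at no more than three loci and
    the M1 subtypes ordered M1-2 < M1-1 < M1-0 by distance from m0-0.
    """
    if path is None:
        path = load_fixture_path("m_haplotypes_synthetic.csv")
    haps = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        for row in reader:
            alleles = tuple(
                None if v.strip() in {"", "?"} else float(v) for v in row[1:]
            )
            haps.append(MHaplotype(row[0], alleles))
    return haps


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class SSRGenotypeMatrix:
    """Accession x marker matrix of unordered allele-size pairs.

    ``genotypes[accession][k]`` is an unordered pair (tuple, sorted) of sizes
    for marker ``k`` or ``None`` for a missing call.
    """

    markers: list[str]
    genotypes: dict[str, list[tuple[float, float] | None]]

    def __post_init__(self) -> None:
        for acc, row in self.genotypes.items():
            if len(row) != len(self.markers):
                raise GermplasmError(
                    f"{acc}: expected {len(self.markers)} marker genotypes"
                )
            self.genotypes[acc] = [
                None if g is None else tuple(sorted(g)) for g in row
            ]

    @classmethod
    def from_csv(cls, path: str | Path) -> "SSRGenotypeMatrix":
        """Read accession rows with two columns per marker (``<m>_a``, ``<m>_b``)."""
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            cols = [c for c in reader.fieldnames or [] if c != "accession"]
            markers = sorted({c[:-2] for c in cols if c.endswith(("_a", "_b"))},
                             key=cols.index)
            genotypes = {}
            for row in reader:
                entry = []
                for m in markers:
                    a, b = row.get(f"{m}_a", ""), row.get(f"{m}_b", "")
                    if a.strip() and b.strip():
                        entry.append((float(a), float(b)))
                    else:
                        entry.append(None)
                genotypes[row["accession"]] = entry
        return cls(markers, genotypes)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            header = ["accession"]
            for m in self.markers:
                header += [f"{m}_a", f"{m}_b"]
            w.writerow(header)
            for acc, row in self.genotypes.items():
                out = [acc]
                for g in row:
                    out += ["", ""] if g is None else [g[0], g[1]]
                w.writerow(out)


def _phase_completions(
    genotype: Sequence[tuple[float, float] | None]
) -> list[tuple[Alleles, Alleles]]:
    """All (h1, h2) phase splits of one multilocus genotype.

    Heterozygous loci double the configuration count; the first heterozygous
    locus is fixed to break the global swap symmetry.  Missing loci propagate
    as None into both haplotypes.
    """
    het_idx = [
        i for i, g in enumerate(genotype) if g is not None and g[0] != g[1]
    ]
    results = []
    n_free = max(len(het_idx) - 1, 0)
    for bits in itertools.product((0, 1), repeat=n_free):
        h1, h2 = [], []
        flips = dict(zip(het_idx[1:], bits))
        for i, g in enumerate(genotype):
            if g is None:
                h1.append(None)
                h2.append(None)
            elif g[0] == g[1]:
                h1.append(g[0])
                h2.append(g[1])
            else:
                flip = flips.get(i, 0)
                h1.append(g[flip])
                h2.append(g[1 - flip])
        results.append((tuple(h1), tuple(h2)))
    return results


# ---------------------------------------------------------------------------
# Phasing from progeny
# ---------------------------------------------------------------------------

@dataclass
class PhaseResult:
    phased: tuple[Alleles, Alleles] | None
    n_explained: int
    n_exceptions: int
    unphased: bool = False
    tied_candidates: list[tuple[Alleles, Alleles]] = field(default_factory=list)


def _gamete_compatible(gamete: Alleles, genotype, other_gametes) -> bool:
    return any(
        _pair_matches(gamete, og, genotype) for og in other_gametes
    )


def _pair_matches(h1: Alleles, h2: Alleles, genotype) -> bool:
    """Do two gametes jointly explain an observed multilocus genotype?"""
    for a, b, g in zip(h1, h2, genotype):
        if g is None or a is None or b is None:
            continue
        if tuple(sorted((a, b))) != g:
            return False
    return True


def phase_from_progeny(
    parent_genotype: Sequence[tuple[float, float] | None],
    progeny: SSRGenotypeMatrix,
    *,
    other_parent_haplotypes: Sequence[Alleles] | None = None,
) -> PhaseResult:
    """Phase a parent's M-locus genotype by co-transmission in its progeny.

    With the seven markers fully linked, each progeny inherits one intact
    parental haplotype per gamete.  Every candidate phase split is scored by
    the number of progeny explainable without recombination; the maximising
    split wins, progeny that no split explains are counted as
    recombination/mutation exceptions, and ties return an unphased result.
    For a selfing both gametes come from the parent; for an outcross supply
    ``other_parent_haplotypes``.
    """
    candidates = _phase_completions(parent_genotype)
    if len(candidates) == 1:
        h1, h2 = candidates[0]
        n_exp, n_exc = _score_phase(h1, h2, progeny, other_parent_haplotypes)
        return PhaseResult((h1, h2), n_exp, n_exc)

    scores = []
    for h1, h2 in candidates:
        n_exp, n_exc = _score_phase(h1, h2, progeny, other_parent_haplotypes)
        scores.append((n_exp, (h1, h2), n_exc))
    best = max(s[0] for s in scores)
    winners = [s for s in scores if s[0] == best]
    if len(winners) > 1:
        return PhaseResult(
            None, best, winners[0][2], unphased=True,
            tied_candidates=[w[1] for w in winners],
        )
    n_exp, pair, n_exc = winners[0]
    return PhaseResult(pair, n_exp, n_exc)


def _score_phase(h1, h2, progeny, other_parent_haplotypes):
    own = (h1, h2)
    other = other_parent_haplotypes if other_parent_haplotypes is not None else own
    n_exp = 0
    n_exc = 0
    for genotype in progeny.genotypes.values():
        ok = any(
            _pair_matches(g1, g2, genotype)
            for g1 in own for g2 in other
        )
        if ok:
            n_exp += 1
        else:
            n_exc += 1
    return n_exp, n_exc


# ---------------------------------------------------------------------------
# EM haplotype-frequency inference
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeFrequencyEstimate:
    frequencies: dict[Alleles, float]
    log_likelihood: list[float]
    best_pairs: dict[str, tuple[Alleles, Alleles, float]]  # acc -> (h1, h2, posterior)
    converged: bool
    n_iter: int
    excluded: list[str] = field(default_factory=list)


def _compatible(hap: Alleles, genotype, partner_of=None) -> bool:
    for a, g in zip(hap, genotype):
        if g is None or a is None:
            continue
        if a not in g:
            return False
    return True


def _pair_compatible(h1: Alleles, h2: Alleles, genotype) -> bool:
    for a, b, g in zip(h1, h2, genotype):
        if g is None:
            continue
        if a is None or b is None:
            continue
        if tuple(sorted((a, b))) != g:
            return False
    return True


def em_haplotype_inference(
    matrix: SSRGenotypeMatrix,
    *,
    known: Iterable[MHaplotype] | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> HaplotypeFrequencyEstimate:
    """Multilocus haplotype frequencies by expectation-maximisation.

    The support set is built from all phase completions of fully observed
    genotypes plus any ``known`` reference haplotypes; genotypes with missing
    loci contribute through marginalisation over compatible support pairs.
    Initialisation is uniform over the support.  The log-likelihood is
    asserted non-decreasing every iteration and convergence is a gain below
    ``tol``; hitting ``max_iter`` flags the result as non-converged.
    """
    if len(matrix.genotypes) < 2:
        raise GermplasmError("EM inference needs at least two accessions")

    support: set[Alleles] = set()
    if known:
        support.update(h.alleles for h in known)
    complete = {
        acc: g for acc, g in matrix.genotypes.items()
        if all(x is not None for x in g)
    }
    for g in complete.values():
        for h1, h2 in _phase_completions(g):
            support.add(h1)
            support.add(h2)
    support_list = sorted(support, key=lambda h: tuple(-1 if a is None else a for a in h))
    if not support_list:
        raise GermplasmError("no haplotype support could be constructed")

    # Pre-compute compatible pairs per accession.
    pair_index: dict[str, list[tuple[int, int]]] = {}
    excluded: list[str] = []
    for acc, g in matrix.genotypes.items():
        pairs = [
            (i, j)
            for i in range(len(support_list))
            for j in range(i, len(support_list))
            if _pair_compatible(support_list[i], support_list[j], g)
        ]
        if pairs:
            pair_index[acc] = pairs
        else:
            excluded.append(acc)

    n_h = len(support_list)
    freqs = np.full(n_h, 1.0 / n_h)
    loglik_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros(n_h)
        loglik = 0.0
        for acc, pairs in pair_index.items():
            weights = np.array([
                (1.0 if i == j else 2.0) * freqs[i] * freqs[j]
                for i, j in pairs
            ])
            total = weights.sum()
            if total <= 0:
                continue
            loglik += math.log(total)
            weights /= total
            for (i, j), w in zip(pairs, weights):
                expected[i] += w
                expected[j] += w
        new_freqs = expected / expected.sum()
        if loglik_trace and loglik < loglik_trace[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        gain = loglik - loglik_trace[-1] if loglik_trace else math.inf
        loglik_trace.append(loglik)
        freqs = new_freqs
        assert abs(freqs.sum() - 1.0) < 1e-10
        if gain < tol:
            converged = True
            break

    best_pairs = {}
    for acc, pairs in pair_index.items():
        weights = [
            ((1.0 if i == j else 2.0) * freqs[i] * freqs[j], i, j)
            for i, j in pairs
        ]
        total = sum(w for w, _, _ in weights)
        w, i, j = max(weights, key=lambda t: t[0])
        best_pairs[acc] = (
            support_list[i], support_list[j], (w / total if total > 0 else 0.0)
        )
    freq_map = {
        h: f for h, f in zip(support_list, freqs) if f > 1e-12
    }
    return HaplotypeFrequencyEstimate(
        freq_map, loglik_trace, best_pairs, converged, it, excluded
    )


# ---------------------------------------------------------------------------
# Main classes
# ---------------------------------------------------------------------------

@dataclass
class MainClassAssignment:
    classes: dict[str, int]  # haplotype label -> class index
    subtypes: dict[str, int]  # haplotype label -> subtype index within class
    members: list[list[str]]  # class index -> member labels
    excluded: list[str]  # haplotypes with >50% missing loci

    @property
    def n_classes(self) -> int:
        return len(self.members)

    def render(self, label: str) -> str:
        """Two-index label ``C<class>-<subtype>`` for an assigned haplotype."""
        return f"C{self.classes[label]}-{self.subtypes[label]}"


def assign_main_classes(
    haplotypes: Sequence[MHaplotype],
    *,
    max_diff: int = 3,
) -> MainClassAssignment:
    """Group haplotypes into main classes by single linkage.

    Two haplotypes are joined when they differ at no more than ``max_diff``
    of the shared observed loci; classes are the connected components of the
    resulting graph.  The pairwise rule is not transitive, so components give
    the unique order-independent closure.  Classes are numbered by their
    lexicographically smallest member allele vector, subtypes within a class
    likewise, making the assignment deterministic and input-order invariant.
    Haplotypes missing more than half their loci are excluded and reported.
    """
    n_loci = len(haplotypes[0].alleles) if haplotypes else 0
    usable = []
    excluded = []
    for h in haplotypes:
        if n_loci and h.n_missing() > n_loci // 2:
            excluded.append(h.label)
        else:
            usable.append(h)

    graph = nx.Graph()
    graph.add_nodes_from(h.label for h in usable)
    for h1, h2 in itertools.combinations(usable, 2):
        if h1.differences(h2) <= max_diff:
            graph.add_edge(h1.label, h2.label)

    by_label = {h.label: h for h in usable}

    def vec_key(label: str):
        return tuple(
            (math.inf if a is None else a) for a in by_label[label].alleles
        )

    components = [sorted(c, key=vec_key) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: vec_key(c[0]))

    classes: dict[str, int] = {}
    subtypes: dict[str, int] = {}
    for ci, comp in enumerate(components):
        for si, label in enumerate(comp):
            classes[label] = ci
            subtypes[label] = si
    return MainClassAssignment(classes, subtypes, components, excluded)
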