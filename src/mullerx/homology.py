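"""Muller-element homology calling and sex-chromosome event classification.

Chromosome–element homology is inferred from shared gene content.  Under
independence, the number of genes expected to be shared by a chromosome of
the target species and a Muller element of the reference is

    N_expected = P1 * P2 * N_total,

where P1 and P2 are the proportions of mapped genes on the element and the
chromosome, and N_total is the number of genes mapped in both species.  A
chromosome is called homologous to an element when the observed count
exceeds 1.5x this expectation (strictly) and the excess is significant by a
one-sided Fisher's exact test.

From the homology calls per species, the X complement (which elements sit
on the X chromosome(s)) classifies the species into sex-chromosome event
classes: ancestral X (element F alone), X–autosome fusion (F plus others),
or turnover (F no longer X-linked), with the autosomal fate of F recorded.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_mapping import MULLER_ELEMENTS, UNKNOWN_ELEMENT, GeneMapTable

logger = logging.getLogger("mullerx")

UNPLACED = "unplaced"


# ---------------------------------------------------------------------------
# Shared-gene counts and the expectation
# ---------------------------------------------------------------------------

def expected_shared_count(p1: float, p2: float, n_total: int) -> float:
    """Expected shared genes between a chromosome pair under independence."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    return p1 * p2 * n_total


@dataclass
class SharedGeneCounts:
    """Gene-sharing count matrix between a reference and a target species.

    ``counts`` has reference Muller elements as rows and target chromosomes
    as columns; genes on unassembled target scaffolds are pooled in an
    ``unplaced`` pseudo-column that is excluded from margins and tests.
    """

    species_ref: str
    species_target: str
    counts: pd.DataFrame
    n_total: int

    @property
    def placed_counts(self) -> pd.DataFrame:
        cols = [c for c in self.counts.columns if c != UNPLACED]
        return self.counts[cols]

    @property
    def n_placed(self) -> int:
        return int(self.placed_counts.values.sum())


def enrichment_table(
    map_ref: GeneMapTable | Mapping[str, str],
    map_target: GeneMapTable,
) -> SharedGeneCounts:
    """Cross-tabulate shared genes: reference element x target chromosome.

    ``map_ref`` may be a full gene-map table or simply the reference
    ``gene_id -> element`` labelling.  N_total is the number of genes mapped
    in both species.
    """
    if isinstance(map_ref, GeneMapTable):
        ref_elements = {r.gene_id: r.muller_element for r in map_ref.records}
        ref_name = map_ref.species_id
    else:
        ref_elements = dict(map_ref)
        ref_name = "reference"

    placed = map_target.placed_chromosomes()
    rows: list[tuple[str, str]] = []
    for rec in map_target.records:
        element = ref_elements.get(rec.gene_id)
        if element is None:
            continue
        chrom = rec.chromosome if rec.chromosome in placed else UNPLACED
        rows.append((element, chrom))
    if not rows:
        raise ValueError(
            f"no shared genes between {ref_name} and {map_target.species_id}"
        )
    df = pd.DataFrame(rows, columns=["element", "chromosome"])
    counts = pd.crosstab(df["element"], df["chromosome"])
    counts.index.name = "element"
    counts.columns.name = "chromosome"
    return SharedGeneCounts(
        species_ref=ref_name,
        species_target=map_target.species_id,
        counts=counts,
        n_total=len(rows),
    )


# ---------------------------------------------------------------------------
# Homology calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyCall:
    chromosome: str
    element: str
    observed: int
    expected: float
    ratio: float
    fisher_p: float
    is_homologous: bool


#: fewer shared genes than this cannot support a homology call (a single
#: shared gene is "too few" to determine homology)
MIN_OBSERVED_FOR_CALL = 2


def call_homology(
    counts: SharedGeneCounts,
    ratio_threshold: float = 1.5,
    alpha: float = 0.05,
    min_observed: int = MIN_OBSERVED_FOR_CALL,
    bh_correct: bool = False,
) -> list[HomologyCall]:
    """Call element–chromosome homology from a shared-gene count matrix.

    A pair is homologous when observed/expected strictly exceeds
    ``ratio_threshold`` AND the one-sided (greater) Fisher exact p on the
    2x2 table [on-element & on-chrom, on-element & off-chrom; off & on,
    off & off] is below ``alpha``, with at least ``min_observed`` shared
    genes.  Unplaced genes are excluded from both margins.  Optional
    Benjamini–Hochberg correction across pairs (off by default).
    """
    table = counts.placed_counts
    n = counts.n_placed
    if n == 0:
        raise ValueError("no placed shared genes")
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    calls: list[HomologyCall] = []
    for element in table.index:
        for chrom in table.columns:
            obs = int(table.loc[element, chrom])
            if obs < 1:
                continue
            exp = expected_shared_count(row_tot[element] / n, col_tot[chrom] / n, n)
            ratio = obs / exp if exp > 0 else math.inf
            a = obs
            b = int(row_tot[element]) - obs
            c = int(col_tot[chrom]) - obs
            d = n - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            calls.append(
                HomologyCall(
                    chromosome=str(chrom),
                    element=str(element),
                    observed=obs,
                    expected=exp,
                    ratio=ratio,
                    fisher_p=float(p),
                    is_homologous=False,
                )
            )
    pvals = np.array([c.fisher_p for c in calls])
    if bh_correct and len(pvals):
        pvals = _benjamini_hochberg(pvals)
    out: list[HomologyCall] = []
    for call, p_adj in zip(calls, pvals):
        homologous = (
            call.ratio > ratio_threshold
            and p_adj < alpha
            and call.observed >= min_observed
        )
        out.append(
            HomologyCall(
                chromosome=call.chromosome,
                element=call.element,
                observed=call.observed,
                expected=call.expected,
                ratio=call.ratio,
                fisher_p=float(p_adj),
                is_homologous=homologous,
            )
        )
    return out


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Karyotype / event classification
# ---------------------------------------------------------------------------

class EventClass(str, enum.Enum):
    ANCESTRAL_X = "ancestral_X"
    X_AUTOSOME_FUSION = "X_autosome_fusion"
    TURNOVER = "turnover"
    TURNOVER_WITH_F_FUSION = "turnover_with_F_fusion"
    F_REVERTED_UNFUSED = "F_reverted_unfused"
    UNRESOLVED = "unresolved"


class FFate(str, enum.Enum):
    ON_X = "on_X"
    FUSED_AUTOSOME = "fused_autosome"
    INDEPENDENT_AUTOSOME = "independent_autosome"
    UNRESOLVED = "unresolved"


@dataclass
class KaryotypeCall:
    species_id: str
    element_map: dict[str, set[str]]
    x_chromosomes: set[str]
    x_elements: set[str]
    event_class: EventClass
    f_fate: FFate

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "element_map": {c: sorted(e) for c, e in self.element_map.items()},
            "x_chromosomes": sorted(self.x_chromosomes),
            "x_elements": sorted(self.x_elements),
            "event_class": self.event_class.value,
            "f_fate": self.f_fate.value,
        }


def infer_karyotype(
    calls: Iterable[HomologyCall],
    x_chromosomes: set[str],
    species_id: str = "",
    f_element: str = "F",
) -> KaryotypeCall:
    """Classify a species' sex-chromosome state from its homology calls.

    Element F alone on the X -> ancestral X; F plus other element(s) on the
    X -> X–autosome fusion; F off the X -> turnover, subdivided by the
    autosomal fate of F (fused to another element, reverted to an
    independent autosome, or not confidently placed).
    """
    element_map: dict[str, set[str]] = {}
    for call in calls:
        if call.is_homologous:
            element_map.setdefault(call.chromosome, set()).add(call.element)

    x_elements: set[str] = set()
    for chrom in x_chromosomes:
        x_elements |= element_map.get(chrom, set())

    if not x_elements:
        logger.warning("%s: no element confidently assigned to the X", species_id)
        return KaryotypeCall(
            species_id, element_map, set(x_chromosomes), x_elements,
            EventClass.UNRESOLVED, FFate.UNRESOLVED,
        )

    if f_element in x_elements:
        event = (
            EventClass.ANCESTRAL_X if len(x_elements) == 1 else EventClass.X_AUTOSOME_FUSION
        )
        return KaryotypeCall(
            species_id, element_map, set(x_chromosomes), x_elements, event, FFate.ON_X
        )

    # turnover: F no longer X-linked; find its autosomal fate
    f_chroms = [
        c for c, els in element_map.items()
        if f_element in els and c not in x_chromosomes
    ]
    if not f_chroms:
        return KaryotypeCall(
            species_id, element_map, set(x_chromosomes), x_elements,
            EventClass.TURNOVER, FFate.UNRESOLVED,
        )
    fused = any(len(element_map[c]) > 1 for c in f_chroms)
    if fused:
        return KaryotypeCall(
            species_id, element_map, set(x_chromosomes), x_elements,
            EventClass.TURNOVER_WITH_F_FUSION, FFate.FUSED_AUTOSOME,
        )
    return KaryotypeCall(
        species_id, element_map, set(x_chromosomes), x_elements,
        EventClass.TURNOVER, FFate.INDEPENDENT_AUTOSOME,
    )


# ---------------------------------------------------------------------------
# Fusion origin counting and the random-pairing expectation
# ---------------------------------------------------------------------------

def count_fusion_origins(tree, fusion_presence: Mapping[str, bool]) -> int:
    """Minimum number of independent fusion origins on a family tree.

    Parsimony with the unfused state ancestral at the root and losses
    allowed: among reconstructions minimising total state changes (root
    fixed at absence), returns the minimum number of 0->1 (origin) edges.
    Accepts a :class:`~mullerx.phylo.Phylogeny` or a dendropy Tree.
    """
    from .phylo import Phylogeny  # local import to avoid a cycle

    if not isinstance(tree, Phylogeny):
        tree = Phylogeny.from_dendropy(tree)
    tips = set(tree.tip_labels)
    missing = set(fusion_presence) - tips
    if missing:
        raise ValueError(f"states given for unknown tips: {sorted(missing)}")

    INF = (10**9, 10**9)
    # cost[node][state] = (total changes, origin edges) over subtree, lexicographic
    cost = [[INF, INF] for _ in range(tree.n_nodes)]
    for idx in tree.postorder:
        if tree.is_tip[idx]:
            state = 1 if fusion_presence.get(tree.labels[idx], False) else 0
            cost[idx][state] = (0, 0)
            continue
        for s in (0, 1):
            total = [0, 0]
            ok = True
            for child in tree.children[idx]:
                best = INF
                for cs in (0, 1):
                    base = cost[child][cs]
                    if base == INF:
                        continue
                    changes = base[0] + (1 if cs != s else 0)
                    origins = base[1] + (1 if (s, cs) == (0, 1) else 0)
                    cand = (changes, origins)
                    if cand < best:
                        best = cand
                if best == INF:
                    ok = False
                    break
                total[0] += best[0]
                total[1] += best[1]
            cost[idx][s] = tuple(total) if ok else INF
    root_cost = cost[tree.root][0]  # absence ancestral
    return root_cost[1]


def expected_fusion_split(
    n_fusions: int,
    n_elements: int = 6,
    n_x_elements: int = 1,
) -> tuple[float, float]:
    """Expected split of fusions into X-involving vs autosome–autosome.

    Under random joining of two distinct Muller elements, the chance that a
    fusion involves the X equals the fraction of unordered element pairs
    containing an X-linked element, found by enumerating all pairs.  For 8
    fusions among 6 elements with one X this gives (2.667, 5.333).
    """
    if n_elements < 2:
        raise ValueError("need at least two elements")
    if not (1 <= n_x_elements < n_elements):
        raise ValueError("n_x_elements must be in [1, n_elements)")
    if n_fusions < 0:
        raise ValueError("n_fusions must be non-negative")
    x_set = set(range(n_x_elements))
    pairs = [(i, j) for i in range(n_elements) for j in range(i + 1, n_elements)]
    with_x = sum(1 for i, j in pairs if i in x_set or j in x_set)
    p_x = with_x / len(pairs)
    expected_x = n_fusions * p_x
    return expected_x, n_fusions - expected_x


@dataclass
class FusionTally:
    n_x_fusions: int
    n_aa_fusions: int
    expected_x: float
    expected_aa: float
    n_elements: int = 6


def fusion_tally(
    n_x_fusions: int,
    n_aa_fusions: int,
    n_elements: int = 6,
    n_x_elements: int = 1,
) -> FusionTally:
    """Observed fusion counts alongside their random-pairing expectation."""
    total = n_x_fusions + n_aa_fusions
    exp_x, exp_aa = expected_fusion_split(total, n_elements, n_x_elements)
    return FusionTally(n_x_fusions, n_aa_fusions, exp_x, exp_aa, n_elements)


def coopt_binomial_test(
    coopt_counts: Mapping[str, int],
    n_candidate_elements: int = 5,
    n_reps: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo test for over-representation of one element as a new X.

    Under the null, the observed co-option events fall uniformly on the
    candidate elements; the p-value is the probability that the maximum
    per-element count reaches the observed maximum.  Max-statistic
    construction, reproducible given ``seed``.
    """
    counts = [int(v) for v in coopt_counts.values()]
    if any(v < 0 for v in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all co-option counts are zero")
    if n_reps < 1000:
        raise ValueError("n_reps must be at least 1000")
    obs_max = max(counts)
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(total, [1 / n_candidate_elements] * n_candidate_elements, size=n_reps)
    return float(np.mean(sims.max(axis=1) >= obs_max))


# ---------------------------------------------------------------------------
# Gene-fate tracing (minute-X style analyses)
# ---------------------------------------------------------------------------

ABSENT = "absent"


def trace_gene_fate(
    anchor_genes: Iterable[str],
    tables: Sequence[GeneMapTable],
    target_chromosomes: Mapping[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Track a set of anchor genes across species tables.

    Returns a genes x species matrix of placement strings
    (``chromosome|element``, ``unplaced`` or ``absent``) and a per-gene
    summary: ``on_target`` when the gene lands on one of the species'
    designated target chromosomes in at least one species, ``elsewhere``
    when present somewhere but never on a target, ``absent`` otherwise.
    ``target_chromosomes`` maps species_id -> chromosomes of interest (for
    example the chromosomes homologous to element F).
    """
    anchors = sorted(set(anchor_genes))
    if not anchors:
        raise ValueError("anchor gene set is empty")
    target_chromosomes = target_chromosomes or {}
    cells: dict[str, dict[str, str]] = {g: {} for g in anchors}
    category: dict[str, str] = {g: ABSENT for g in anchors}
    for table in tables:
        placed = table.placed_chromosomes()
        targets = target_chromosomes.get(table.species_id, set())
        by_gene = {r.gene_id: r for r in table.records}
        for g in anchors:
            rec = by_gene.get(g)
            if rec is None:
                cells[g][table.species_id] = ABSENT
                continue
            if rec.chromosome not in placed:
                cells[g][table.species_id] = UNPLACED
                if category[g] == ABSENT:
                    category[g] = "elsewhere"
                continue
            cells[g][table.species_id] = f"{rec.chromosome}|{rec.muller_element}"
            if rec.chromosome in targets:
                category[g] = "on_target"
            elif category[g] == ABSENT:
                category[g] = "elsewhere"
    matrix = pd.DataFrame(cells).T
    matrix.index.name = "gene_id"
    return matrix, pd.Series(category, name="fate")
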