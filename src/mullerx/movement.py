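"""Trio-based gene-movement inference and the size-weighted expectation null.

A trio consists of a focal species with a newly derived X plus two
independent outgroups that retain element F as their X.  Chromosome
correspondence between each outgroup and the focal species is established
by the 1.5x shared-gene enrichment rule; a gene's ancestral location is
the focal chromosome both outgroup placements map to (disagreement or a
missing/unplaced copy leaves it undetermined), and movement is called
when the focal placement differs from that ancestral location.

Observed movements per category (X->A, A->X, A->A) are tested against a
random-relocation null in which the expected number of moves from
chromosome i to chromosome j is proportional to

    N_i * L_j * f_ij,

with N_i the gene count of the source chromosome, L_j the length of the
destination, and f_ij = 1 for autosomal destinations and 0.75 for X
destinations (the X spends less time in the population than an autosome).
Significance comes from a chi-square goodness-of-fit test over the
category bins.  Expression of moved genes is compared to all mapped genes
per tissue with two-sided Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homology import expected_shared_count
from .io_mapping import GeneMapTable

logger = logging.getLogger("mullerx")

X_DESTINATION_WEIGHT = 0.75


# ---------------------------------------------------------------------------
# Chromosome correspondence
# ---------------------------------------------------------------------------

def match_chromosomes(
    map_a: GeneMapTable,
    map_b: GeneMapTable,
    threshold: float = 1.5,
) -> dict[str, str]:
    """Chromosome correspondence a -> b by shared-gene enrichment.

    Pairs with observed/expected strictly above ``threshold`` are
    candidates; each a-chromosome keeps only its highest-ratio partner
    (so two fused source chromosomes may both map to one target).  Only
    placed chromosomes participate.
    """
    placed_a = map_a.placed_chromosomes()
    placed_b = map_b.placed_chromosomes()
    loc_a = {r.gene_id: r.chromosome for r in map_a.records if r.chromosome in placed_a}
    loc_b = {r.gene_id: r.chromosome for r in map_b.records if r.chromosome in placed_b}
    shared = sorted(set(loc_a) & set(loc_b))
    if not shared:
        raise ValueError(
            f"no shared placed genes between {map_a.species_id} and {map_b.species_id}"
        )
    df = pd.DataFrame(
        {"a": [loc_a[g] for g in shared], "b": [loc_b[g] for g in shared]}
    )
    counts = pd.crosstab(df["a"], df["b"])
    n = len(shared)
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    best: dict[str, tuple[float, str]] = {}
    for ca in counts.index:
        for cb in counts.columns:
            obs = int(counts.loc[ca, cb])
            if obs == 0:
                continue
            exp = expected_shared_count(row_tot[ca] / n, col_tot[cb] / n, n)
            ratio = obs / exp
            if ratio > threshold:
                cur = best.get(ca)
                if cur is None or ratio > cur[0]:
                    best[ca] = (ratio, str(cb))
    if not best:
        logger.warning(
            "no chromosome pair above %.2fx enrichment between %s and %s",
            threshold, map_a.species_id, map_b.species_id,
        )
    return {a: b for a, (_, b) in best.items()}


@dataclass
class TrioConfig:
    """A focal species plus two outgroups with correspondence maps.

    ``corr_out1`` / ``corr_out2`` map outgroup chromosomes to focal
    chromosomes (partial functions: unmatched chromosomes are absent).
    """

    focal: str
    outgroup1: str
    outgroup2: str
    corr_out1: dict[str, str]
    corr_out2: dict[str, str]
    focal_x: set[str] = field(default_factory=set)


def build_trio(
    focal_table: GeneMapTable,
    out1_table: GeneMapTable,
    out2_table: GeneMapTable,
    focal_x: set[str],
    threshold: float = 1.5,
) -> TrioConfig:
    """Assemble a trio configuration by matching each outgroup to the focal."""
    return TrioConfig(
        focal=focal_table.species_id,
        outgroup1=out1_table.species_id,
        outgroup2=out2_table.species_id,
        corr_out1=match_chromosomes(out1_table, focal_table, threshold),
        corr_out2=match_chromosomes(out2_table, focal_table, threshold),
        focal_x=set(focal_x),
    )


# ---------------------------------------------------------------------------
# Movement calls
# ---------------------------------------------------------------------------

class MovementCategory(str, enum.Enum):
    X_TO_A = "X_to_A"
    A_TO_X = "A_to_X"
    A_TO_A = "A_to_A"
    X_TO_X = "X_to_X"
    NONE = "none"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class MovementCall:
    gene_id: str
    ancestral_chrom: str | None  # focal-coordinates ancestral chromosome
    focal_chrom: str | None
    category: MovementCategory


def infer_ancestral_location(
    gene: str,
    out1_chrom: str | None,
    out2_chrom: str | None,
    corr1: Mapping[str, str],
    corr2: Mapping[str, str],
) -> str | None:
    """Ancestral location of a gene in focal coordinates, or None.

    Both outgroup placements must exist and map (via the correspondence
    maps) to the same focal chromosome; anything else leaves the ancestral
    location undetermined.
    """
    if out1_chrom is None or out2_chrom is None:
        return None
    anc1 = corr1.get(out1_chrom)
    anc2 = corr2.get(out2_chrom)
    if anc1 is None or anc2 is None or anc1 != anc2:
        return None
    return anc1


def call_movements(
    trio: TrioConfig,
    focal_table: GeneMapTable,
    out1_table: GeneMapTable,
    out2_table: GeneMapTable,
) -> list[MovementCall]:
    """Per-gene movement calls for all genes mapped in the focal species.

    The X/autosome class of a chromosome is its identity in the focal
    species: a gene that stayed on the same chromosome counts as ``none``
    even if that chromosome was newly co-opted as the X.  Genes on
    unplaced scaffolds in any trio member, absent from an outgroup, or
    with disagreeing outgroups are ``undetermined``.
    """
    placed_f = focal_table.placed_chromosomes()
    placed_1 = out1_table.placed_chromosomes()
    placed_2 = out2_table.placed_chromosomes()
    loc1 = {
        r.gene_id: (r.chromosome if r.chromosome in placed_1 else None)
        for r in out1_table.records
    }
    loc2 = {
        r.gene_id: (r.chromosome if r.chromosome in placed_2 else None)
        for r in out2_table.records
    }
    x_set = trio.focal_x
    calls: list[MovementCall] = []
    for rec in focal_table.records:
        g = rec.gene_id
        focal_chrom = rec.chromosome if rec.chromosome in placed_f else None
        anc = infer_ancestral_location(
            g, loc1.get(g), loc2.get(g), trio.corr_out1, trio.corr_out2
        )
        if focal_chrom is None or anc is None:
            calls.append(MovementCall(g, anc, focal_chrom, MovementCategory.UNDETERMINED))
            continue
        if focal_chrom == anc:
            calls.append(MovementCall(g, anc, focal_chrom, MovementCategory.NONE))
            continue
        src_x = anc in x_set
        dst_x = focal_chrom in x_set
        if src_x and not dst_x:
            cat = MovementCategory.X_TO_A
        elif not src_x and dst_x:
            cat = MovementCategory.A_TO_X
        elif not src_x and not dst_x:
            cat = MovementCategory.A_TO_A
        else:
            cat = MovementCategory.X_TO_X
        calls.append(MovementCall(g, anc, focal_chrom, cat))
    return calls


def movement_counts(calls: Iterable[MovementCall]) -> dict[str, int]:
    """Observed moves per category (excludes ``none``/``undetermined``)."""
    counts = {c.value: 0 for c in (
        MovementCategory.A_TO_A, MovementCategory.A_TO_X, MovementCategory.X_TO_A
    )}
    for call in calls:
        if call.category in (MovementCategory.NONE, MovementCategory.UNDETERMINED):
            continue
        counts.setdefault(call.category.value, 0)
        counts[call.category.value] += 1
    return counts


# ---------------------------------------------------------------------------
# The expectation null
# ---------------------------------------------------------------------------

@dataclass
class MovementExpectation:
    observed: dict[str, int]
    expected: dict[str, float]
    proportions: dict[str, float]
    n_genes: dict[str, int]
    lengths: dict[str, int]
    x_set: set[str]
    total_moves: int
    chi2: float | None = None
    df: int | None = None
    p: float | None = None


def expected_movement_counts(
    n_genes: Mapping[str, int],
    lengths: Mapping[str, int],
    x_set: set[str],
    total_moves: int,
    observed: Mapping[str, int] | None = None,
) -> MovementExpectation:
    """Expected moves per category under size-weighted random relocation.

    Pair weights are N_i * L_j * f_ij over ordered chromosome pairs
    (i != j) with f_ij = 0.75 for X destinations and 1 otherwise,
    normalized over all pairs and binned into categories; expected counts
    are ``total_moves`` times the binned proportions.
    """
    chroms = sorted(n_genes)
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes")
    if total_moves < 0:
        raise ValueError("total_moves must be non-negative")
    missing = set(chroms) - set(lengths)
    if missing:
        raise ValueError(f"missing lengths for {sorted(missing)}")
    bin_weight: dict[str, float] = {}
    total_weight = 0.0
    for i in chroms:
        for j in chroms:
            if i == j:
                continue
            f = X_DESTINATION_WEIGHT if j in x_set else 1.0
            w = n_genes[i] * lengths[j] * f
            src_x, dst_x = i in x_set, j in x_set
            if src_x and not dst_x:
                cat = MovementCategory.X_TO_A.value
            elif not src_x and dst_x:
                cat = MovementCategory.A_TO_X.value
            elif not src_x and not dst_x:
                cat = MovementCategory.A_TO_A.value
            else:
                cat = MovementCategory.X_TO_X.value
            bin_weight[cat] = bin_weight.get(cat, 0.0) + w
            total_weight += w
    if total_weight <= 0:
        raise ValueError("all pair weights are zero")
    proportions = {c: w / total_weight for c, w in bin_weight.items()}
    expected = {c: total_moves * p for c, p in proportions.items()}
    return MovementExpectation(
        observed=dict(observed) if observed is not None else {},
        expected=expected,
        proportions=proportions,
        n_genes=dict(n_genes),
        lengths=dict(lengths),
        x_set=set(x_set),
        total_moves=total_moves,
    )


def movement_chisq(
    observed: Mapping[str, int],
    expectation: MovementExpectation,
) -> tuple[float, int, float]:
    """Pearson chi-square goodness-of-fit of observed vs expected moves."""
    cats = sorted(expectation.expected)
    obs = np.array([observed.get(c, 0) for c in cats], dtype=float)
    exp = np.array([expectation.expected[c] for c in cats], dtype=float)
    if abs(obs.sum() - expectation.total_moves) > 1e-9:
        raise ValueError(
            f"observed moves ({obs.sum():.0f}) do not sum to the total used for "
            f"expectations ({expectation.total_moves})"
        )
    for c, o, e in zip(cats, obs, exp):
        if e == 0 and o > 0:
            raise ValueError(f"expected count is zero for {c} but {o:.0f} observed")
    keep = exp > 0
    obs, exp = obs[keep], exp[keep]
    if np.any(exp < 5):
        logger.warning("chi-square expected count below 5; p-value approximate")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = int(keep.sum()) - 1
    p = float(stats.chi2.sf(chi2, df))
    expectation.chi2, expectation.df, expectation.p = chi2, df, p
    return chi2, df, p


def normalized_loss_fraction(
    moved_out: int,
    ancestral_on_chrom: int,
    frac_genes_elsewhere: float,
) -> float:
    """Fraction of genes moved off a chromosome, normalized by target space.

    Smaller chromosomes see more of the genome as a movement target, so the
    raw loss fraction is divided by the fraction of genes found on other
    chromosomes.
    """
    if ancestral_on_chrom <= 0:
        raise ValueError("ancestral_on_chrom must be positive")
    if not (0.0 < frac_genes_elsewhere <= 1.0):
        raise ValueError("frac_genes_elsewhere must be in (0, 1]")
    return (moved_out / ancestral_on_chrom) / frac_genes_elsewhere


# ---------------------------------------------------------------------------
# Expression comparison
# ---------------------------------------------------------------------------

@dataclass
class ExpressionComparison:
    tissue: str
    n_group: int
    n_all: int
    median_group: float
    median_all: float
    p: float


def compare_expression(
    matrix: pd.DataFrame,
    group: Iterable[str],
    background: Iterable[str],
    tissue: str,
) -> ExpressionComparison:
    """Wilcoxon rank-sum comparison of a gene group vs all mapped genes.

    ``matrix`` is genes x tissues (index = gene ids); ``background`` is
    the full mapped set, inclusive of ``group``.  Two-sided test with tie
    correction.
    """
    group = sorted(set(group))
    background = sorted(set(background))
    if not group:
        raise ValueError("empty gene group")
    if tissue not in matrix.columns:
        raise ValueError(f"tissue {tissue!r} not in expression matrix")
    extra = set(group) - set(background)
    if extra:
        raise ValueError(f"group genes outside background: {sorted(extra)[:5]}")
    g_vals = matrix.loc[[g for g in group if g in matrix.index], tissue].to_numpy(float)
    b_vals = matrix.loc[[g for g in background if g in matrix.index], tissue].to_numpy(float)
    if len(g_vals) == 0 or len(b_vals) == 0:
        raise ValueError("no expression values for group or background")
    res = stats.mannwhitneyu(g_vals, b_vals, alternative="two-sided")
    return ExpressionComparison(
        tissue=tissue,
        n_group=len(g_vals),
        n_all=len(b_vals),
        median_group=float(np.median(g_vals)),
        median_all=float(np.median(b_vals)),
        p=float(res.pvalue),
    )


def load_expression_matrix(path: str) -> pd.DataFrame:
    """Load a genes x tissues TSV (first column gene_id, numeric columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.apply(pd.to_numeric)
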