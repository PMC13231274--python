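"""Synthetic datasets with known ground truth for every pipeline stage.

The generators emulate the structure of real comparative-genomics inputs:
per-species gene-location tables with conserved Muller elements and
planted fusions/turnovers, gene mismapping and unplaced-scaffold noise,
binary turnover characters evolving under regime-dependent Mk rates on a
tree, Brownian continuous traits, base-composition-controlled genome
sequences, species trios with planted inter-chromosomal gene movement,
and expression matrices with a planted testis effect for moved genes.

Every generator is deterministic given its seed, and each emits a truth
table sufficient to score the downstream calls.

Default element-size proportions follow the Schizophora situation: the
ancestral-X element F carries ~1% of mapped genes (non-Schizophora
lineages carry 1.5%–3%, exposed via ``F_PROPORTION_OUTGROUP``), the five
large elements split the rest evenly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_mapping import MULLER_ELEMENTS, GeneMapTable, HitRecord
from .phylo import Phylogeny, RegimeMap, single_regime_map

F_PROPORTION_SCHIZOPHORA = 0.01
F_PROPORTION_OUTGROUP = 0.025

DEFAULT_ELEMENT_PROPORTIONS = {
    "A": 0.198, "B": 0.198, "C": 0.198, "D": 0.198, "E": 0.198,
    "F": F_PROPORTION_SCHIZOPHORA,
}


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """Planted karyotype of one species: chromosome -> elements it carries."""

    species_id: str
    karyotype: dict[str, tuple[str, ...]]
    x_chromosomes: set[str]

    def element_chromosome(self, element: str) -> str | None:
        for chrom, elements in self.karyotype.items():
            if element in elements:
                return chrom
        return None


def ancestral_karyotype(species_id: str, prefix: str = "chr") -> SpeciesSpec:
    """Each element its own chromosome; element F is the X."""
    karyotype = {f"{prefix}{el}": (el,) for el in MULLER_ELEMENTS}
    return SpeciesSpec(species_id, karyotype, {f"{prefix}F"})


def fusion_karyotype(species_id: str, fused_element: str, prefix: str = "chr") -> SpeciesSpec:
    """X–autosome fusion: element F plus ``fused_element`` on one X."""
    karyotype = {
        f"{prefix}{el}": (el,) for el in MULLER_ELEMENTS
        if el not in ("F", fused_element)
    }
    karyotype[f"{prefix}X"] = ("F", fused_element)
    return SpeciesSpec(species_id, karyotype, {f"{prefix}X"})


def turnover_karyotype(
    species_id: str,
    new_x_element: str,
    f_fused_to: str | None = None,
    prefix: str = "chr",
) -> SpeciesSpec:
    """Turnover: ``new_x_element`` becomes the X, F reverts to an autosome.

    With ``f_fused_to`` set, the reverted F is fused to that element's
    autosome instead of standing alone.
    """
    if new_x_element == "F":
        raise ValueError("turnover requires a non-F element as the new X")
    karyotype: dict[str, tuple[str, ...]] = {}
    for el in MULLER_ELEMENTS:
        if el in ("F", new_x_element) or el == f_fused_to:
            continue
        karyotype[f"{prefix}{el}"] = (el,)
    karyotype[f"{prefix}{new_x_element}"] = (new_x_element,)
    if f_fused_to is None:
        karyotype[f"{prefix}F"] = ("F",)
    else:
        karyotype[f"{prefix}{f_fused_to}F"] = (f_fused_to, "F")
    return SpeciesSpec(species_id, karyotype, {f"{prefix}{new_x_element}"})


@dataclass
class SimScenario:
    """Full generative truth for a synthetic dataset."""

    seed: int = 0
    n_genes: int = 2000
    element_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_PROPORTIONS)
    )
    mismap_rate: float = 0.02
    unplaced_rate: float = 0.01
    species: list[SpeciesSpec] = field(default_factory=list)
    movement: dict = field(
        default_factory=lambda: {"n_moves": 0, "out_of_x_excess": 1.0, "new_x_element": "D"}
    )
    tree: dict = field(default_factory=lambda: {"n_tips": 40, "birth_rate": 1.0})
    mk_rates: dict = field(default_factory=lambda: {"all": [0.5, 0.5]})
    bm: dict = field(default_factory=lambda: {"root_value": 2.0, "sigma2": 0.1})
    gc: dict = field(default_factory=lambda: {"chrX": [500_000, 0.45], "chr2": [500_000, 0.40]})
    expression: dict = field(
        default_factory=lambda: {"meanlog": 1.0, "sdlog": 1.0, "testis_multiplier": 2.0}
    )

    def __post_init__(self) -> None:
        total = sum(self.element_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"element proportions must sum to 1 (got {total})")
        for name, p in (("mismap_rate", self.mismap_rate), ("unplaced_rate", self.unplaced_rate)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_genes": self.n_genes,
            "element_proportions": dict(self.element_proportions),
            "mismap_rate": self.mismap_rate,
            "unplaced_rate": self.unplaced_rate,
            "species": [
                {
                    "species_id": s.species_id,
                    "karyotype": {c: list(e) for c, e in s.karyotype.items()},
                    "x_chromosomes": sorted(s.x_chromosomes),
                }
                for s in self.species
            ],
            "movement": dict(self.movement),
            "tree": dict(self.tree),
            "mk_rates": {k: list(v) for k, v in self.mk_rates.items()},
            "bm": dict(self.bm),
            "gc": {c: list(v) for c, v in self.gc.items()},
            "expression": dict(self.expression),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimScenario":
        species = [
            SpeciesSpec(
                species_id=s["species_id"],
                karyotype={c: tuple(e) for c, e in s["karyotype"].items()},
                x_chromosomes=set(s["x_chromosomes"]),
            )
            for s in d.get("species", [])
        ]
        return cls(
            seed=d.get("seed", 0),
            n_genes=d.get("n_genes", 2000),
            element_proportions=dict(d.get("element_proportions", DEFAULT_ELEMENT_PROPORTIONS)),
            mismap_rate=d.get("mismap_rate", 0.02),
            unplaced_rate=d.get("unplaced_rate", 0.01),
            species=species,
            movement=dict(d.get("movement", {})),
            tree=dict(d.get("tree", {})),
            mk_rates={k: tuple(v) for k, v in d.get("mk_rates", {"all": (0.5, 0.5)}).items()},
            bm=dict(d.get("bm", {})),
            gc={c: tuple(v) for c, v in d.get("gc", {}).items()},
            expression=dict(d.get("expression", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_scenario(seed: int = 0) -> SimScenario:
    """The "diptera-small" scenario: 8 species, 2000 genes, 40-tip tree.

    One ancestral species, one X–autosome fusion, two turnovers (one with
    an F fusion) and four more ancestral-karyotype species to anchor the
    homology calls.
    """
    species = [
        ancestral_karyotype("sp_anc1", prefix="s1_"),
        ancestral_karyotype("sp_anc2", prefix="s2_"),
        ancestral_karyotype("sp_anc3", prefix="s3_"),
        ancestral_karyotype("sp_anc4", prefix="s4_"),
        ancestral_karyotype("sp_anc5", prefix="s5_"),
        fusion_karyotype("sp_fusion", "D", prefix="s6_"),
        turnover_karyotype("sp_turnover", "B", prefix="s7_"),
        turnover_karyotype("sp_turnover_ffuse", "D", f_fused_to="E", prefix="s8_"),
    ]
    return SimScenario(seed=seed, species=species)


# ---------------------------------------------------------------------------
# Gene maps
# ---------------------------------------------------------------------------

def element_gene_counts(n_genes: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Integer gene counts per element, totals preserved deterministically."""
    items = sorted(proportions.items())
    counts = {el: int(math.floor(p * n_genes)) for el, p in items}
    remainder = n_genes - sum(counts.values())
    # hand leftovers to the largest elements, stable order
    for el, _ in sorted(items, key=lambda kv: (-kv[1], kv[0]))[:remainder]:
        counts[el] += 1
    return counts


def assign_reference_elements(
    n_genes: int, proportions: Mapping[str, float]
) -> dict[str, str]:
    """Reference gene_id -> element labelling shared by all species."""
    counts = element_gene_counts(n_genes, proportions)
    mapping: dict[str, str] = {}
    i = 0
    for el in sorted(counts):
        for _ in range(counts[el]):
            mapping[f"g{i:05d}"] = el
            i += 1
    return mapping


_GENE_LEN_RANGE = (500, 2500)
_GENE_GAP_RANGE = (100, 1500)


def _lay_out_chromosome(
    genes: Sequence[str],
    elements: Mapping[str, str],
    chrom: str,
    rng: np.random.Generator,
) -> list[HitRecord]:
    """Place genes sequentially with gaps: non-overlapping by construction."""
    records = []
    pos = 0
    order = list(genes)
    rng.shuffle(order)
    for g in order:
        pos += int(rng.integers(*_GENE_GAP_RANGE))
        length = int(rng.integers(*_GENE_LEN_RANGE))
        records.append(
            HitRecord(
                gene_id=g,
                muller_element=elements[g],
                chromosome=chrom,
                start=pos,
                end=pos + length,
                score=int(rng.integers(100, 1000)),
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
        pos += length
    return records


def sim_gene_map(
    spec: SpeciesSpec,
    elements: Mapping[str, str],
    mismap_rate: float,
    unplaced_rate: float,
    rng: np.random.Generator,
) -> tuple[GeneMapTable, pd.DataFrame]:
    """One species' gene-map table plus its per-gene truth.

    Each gene lands on the chromosome carrying its element with
    probability 1 - mismap_rate - unplaced_rate, on a uniformly chosen
    wrong chromosome with probability mismap_rate, and on its own
    unassembled scaffold otherwise.
    """
    genes = sorted(elements)
    chroms = sorted(spec.karyotype)
    true_chrom: dict[str, str] = {}
    for g in genes:
        chrom = spec.element_chromosome(elements[g])
        if chrom is None:
            raise ValueError(f"element {elements[g]} missing from karyotype of {spec.species_id}")
        true_chrom[g] = chrom

    placement: dict[str, str] = {}
    status: dict[str, str] = {}
    n_scaffold = 0
    u = rng.random(len(genes))
    for g, draw in zip(genes, u):
        if draw < unplaced_rate:
            placement[g] = f"scaffold_{n_scaffold}"
            status[g] = "unplaced"
            n_scaffold += 1
        elif draw < unplaced_rate + mismap_rate and len(chroms) > 1:
            wrong = [c for c in chroms if c != true_chrom[g]]
            placement[g] = wrong[int(rng.integers(len(wrong)))]
            status[g] = "mismap"
        else:
            placement[g] = true_chrom[g]
            status[g] = "true"

    by_chrom: dict[str, list[str]] = {}
    for g in genes:
        by_chrom.setdefault(placement[g], []).append(g)

    records: list[HitRecord] = []
    lengths: dict[str, int] = {}
    placed_flag: dict[str, bool] = {}
    for chrom in chroms:
        recs = _lay_out_chromosome(by_chrom.get(chrom, []), elements, chrom, rng)
        records.extend(recs)
        end = max((r.end for r in recs), default=0)
        lengths[chrom] = end + int(rng.integers(1000, 5000))
        placed_flag[chrom] = True
    for chrom, gs in by_chrom.items():
        if chrom in chroms:
            continue
        recs = _lay_out_chromosome(gs, elements, chrom, rng)
        records.extend(recs)
        lengths[chrom] = max(r.end for r in recs) + 100
        placed_flag[chrom] = False

    table = GeneMapTable(
        species_id=spec.species_id,
        records=records,
        chromosome_lengths=lengths,
        placed=placed_flag,
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "element": [elements[g] for g in genes],
            "true_chromosome": [true_chrom[g] for g in genes],
            "observed_chromosome": [placement[g] for g in genes],
            "status": [status[g] for g in genes],
        }
    ).set_index("gene_id")
    return table, truth


def sim_gene_maps(
    scenario: SimScenario,
) -> tuple[dict[str, GeneMapTable], dict[str, str], dict[str, pd.DataFrame]]:
    """Gene-map tables for every species of a scenario, with truth tables.

    Returns (tables by species, reference gene->element map, truth by
    species).  Deterministic for a given scenario seed.
    """
    if not scenario.species:
        raise ValueError("scenario defines no species")
    min_count = min(element_gene_counts(scenario.n_genes, scenario.element_proportions).values())
    if min_count < 1:
        raise ValueError("gene count too small: an element would receive no genes")
    rng = np.random.default_rng(scenario.seed)
    elements = assign_reference_elements(scenario.n_genes, scenario.element_proportions)
    tables: dict[str, GeneMapTable] = {}
    truths: dict[str, pd.DataFrame] = {}
    for spec in scenario.species:
        table, truth = sim_gene_map(
            spec, elements, scenario.mismap_rate, scenario.unplaced_rate, rng
        )
        tables[spec.species_id] = table
        truths[spec.species_id] = truth
    return tables, elements, truths


# ---------------------------------------------------------------------------
# Trees and characters
# ---------------------------------------------------------------------------

class _YuleNode:
    __slots__ = ("children", "blen", "name")

    def __init__(self) -> None:
        self.children: list["_YuleNode"] = []
        self.blen = 0.0
        self.name = ""


def sim_yule_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) tree with exponential waiting times, seeded."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed)
    root = _YuleNode()
    root.children = [_YuleNode(), _YuleNode()]
    active = list(root.children)
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.blen += wait
        k = int(rng.integers(len(active)))
        split = active.pop(k)
        split.children = [_YuleNode(), _YuleNode()]
        active.extend(split.children)
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.blen += wait
    for i, node in enumerate(active):
        node.name = f"t{i}"

    def newick(node: _YuleNode) -> str:
        if not node.children:
            return f"{node.name}:{node.blen:.10g}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{node.blen:.10g}" if node is not root else f"({inner});"

    return Phylogeny.from_newick(newick(root))


def sim_mk_tips(
    tree: Phylogeny,
    rates: Mapping[str, tuple[float, float]] | tuple[float, float],
    regime_map: RegimeMap | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Simulate the binary turnover character down a tree.

    Exponential waiting times along each branch with the branch's regime
    rates; the root state is drawn from a flat prior.
    """
    if regime_map is None:
        regime_map = single_regime_map(tree)
    if isinstance(rates, Mapping):
        rate_list = [tuple(map(float, rates[r])) for r in regime_map.regimes]
    else:
        rate_list = [tuple(map(float, rates))] * regime_map.n_regimes
    rng = np.random.default_rng(seed)
    states = np.empty(tree.n_nodes, dtype=np.int64)
    states[tree.root] = int(rng.random() < 0.5)
    for i in range(tree.n_nodes - 2, -1, -1):  # preorder
        state = states[tree.parent[i]]
        q01, q10 = rate_list[regime_map.branch_regime[i]]
        t = tree.blen[i]
        elapsed = 0.0
        while True:
            rate = q01 if state == 0 else q10
            elapsed += rng.exponential(1.0 / rate) if rate > 0 else math.inf
            if elapsed >= t:
                break
            state = 1 - state
        states[i] = state
    return {tree.labels[i]: int(states[i]) for i in range(tree.n_nodes) if tree.is_tip[i]}


def sim_bm_tips(
    tree: Phylogeny,
    root_value: float,
    sigma2: float,
    seed: int = 0,
    return_internal: bool = False,
):
    """Brownian trait: normal increments with variance sigma2 * branch length."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    values = np.empty(tree.n_nodes)
    values[tree.root] = root_value
    for i in range(tree.n_nodes - 2, -1, -1):
        sd = math.sqrt(sigma2 * tree.blen[i])
        values[i] = values[tree.parent[i]] + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    tips = {tree.labels[i]: float(values[i]) for i in range(tree.n_nodes) if tree.is_tip[i]}
    if return_internal:
        internal = {
            tree.labels[i]: float(values[i])
            for i in range(tree.n_nodes) if not tree.is_tip[i]
        }
        return tips, internal
    return tips


# ---------------------------------------------------------------------------
# Genome sequences
# ---------------------------------------------------------------------------

def sim_sequences(
    gc_spec: Mapping[str, tuple[int, float]],
    seed: int = 0,
    n_block_rate: float = 0.0,
    n_block_len: int = 5000,
) -> dict[str, str]:
    """i.i.d. base sequences with per-chromosome GC means.

    ``gc_spec`` maps chromosome -> (length, gc_mean); P(G)=P(C)=gc/2 and
    P(A)=P(T)=(1-gc)/2.  Optional N blocks are inserted at rate
    ``n_block_rate`` per ``n_block_len`` of sequence.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom in sorted(gc_spec):
        length, gc = gc_spec[chrom]
        if not (0.0 < gc <= 1.0):
            raise ValueError(f"GC mean for {chrom} must be in (0, 1]")
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        arr = rng.choice(bases, size=int(length), p=probs)
        if n_block_rate > 0:
            n_blocks = rng.poisson(n_block_rate * length / n_block_len)
            for _ in range(n_blocks):
                start = int(rng.integers(0, max(1, length - n_block_len)))
                arr[start:start + n_block_len] = ord("N")
        out[chrom] = arr.tobytes().decode("ascii")
    return out


def sim_fasta(
    gc_spec: Mapping[str, tuple[int, float]],
    seed: int = 0,
    n_block_rate: float = 0.0,
    line_width: int = 80,
) -> str:
    """FASTA text for :func:`sim_sequences` output."""
    seqs = sim_sequences(gc_spec, seed=seed, n_block_rate=n_block_rate)
    chunks: list[str] = []
    for name, seq in seqs.items():
        chunks.append(f">{name}")
        for i in range(0, len(seq), line_width):
            chunks.append(seq[i:i + line_width])
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# Trios with planted movement
# ---------------------------------------------------------------------------

def sim_trio(
    seed: int = 0,
    n_genes: int = 2000,
    element_proportions: Mapping[str, float] | None = None,
    new_x_element: str = "D",
    n_moves: int = 0,
    out_of_x_excess: float = 1.0,
    mismap_rate: float = 0.0,
    unplaced_rate: float = 0.0,
) -> tuple[dict[str, GeneMapTable], set[str], pd.DataFrame]:
    """A focal-turnover trio with planted gene movement.

    The two outgroups keep the ancestral karyotype (F as X); the focal
    species co-opted ``new_x_element`` as its X, F reverting to an
    autosome.  ``n_moves`` focal genes are relocated: source/destination
    chromosome pairs are drawn with probability proportional to the
    expectation null's own weights N_i * L_j * f_ij, multiplied by
    ``out_of_x_excess`` for X sources (1.0 reproduces the null exactly).

    Returns (tables keyed 'focal'/'out1'/'out2', focal X chromosomes, and
    the movement truth table with source, destination and category).
    """
    from .movement import MovementCategory, X_DESTINATION_WEIGHT

    props = dict(element_proportions or DEFAULT_ELEMENT_PROPORTIONS)
    rng = np.random.default_rng(seed)
    elements = assign_reference_elements(n_genes, props)
    focal_spec = turnover_karyotype("focal", new_x_element, prefix="f_")
    out1_spec = ancestral_karyotype("out1", prefix="o1_")
    out2_spec = ancestral_karyotype("out2", prefix="o2_")

    # focal table first, noise-free: movement is planted on true placements
    focal_table, _ = sim_gene_map(focal_spec, elements, 0.0, 0.0, rng)
    focal_x = set(focal_spec.x_chromosomes)

    truth_rows: list[tuple[str, str, str, str]] = []
    if n_moves > 0:
        chroms = sorted(focal_spec.karyotype)
        by_chrom: dict[str, list[str]] = {c: [] for c in chroms}
        for rec in focal_table.records:
            by_chrom[rec.chromosome].append(rec.gene_id)
        n_i = {c: len(by_chrom[c]) for c in chroms}
        lengths = focal_table.chromosome_lengths
        pairs: list[tuple[str, str]] = []
        weights: list[float] = []
        for i in chroms:
            for j in chroms:
                if i == j:
                    continue
                f = X_DESTINATION_WEIGHT if j in focal_x else 1.0
                w = n_i[i] * lengths[j] * f
                if i in focal_x:
                    w *= out_of_x_excess
                pairs.append((i, j))
                weights.append(w)
        weights_arr = np.array(weights) / sum(weights)
        moved: dict[str, str] = {}
        available = {c: list(by_chrom[c]) for c in chroms}
        for c in available:
            rng.shuffle(available[c])
        draws = 0
        while len(moved) < n_moves:
            draws += 1
            if draws > 100 * n_moves + 1000:
                raise ValueError("cannot place requested moves: source chromosomes exhausted")
            k = int(rng.choice(len(pairs), p=weights_arr))
            src, dst = pairs[k]
            if not available[src]:
                continue
            g = available[src].pop()
            moved[g] = dst
            src_x, dst_x = src in focal_x, dst in focal_x
            if src_x and not dst_x:
                cat = MovementCategory.X_TO_A
            elif not src_x and dst_x:
                cat = MovementCategory.A_TO_X
            elif not src_x and not dst_x:
                cat = MovementCategory.A_TO_A
            else:
                cat = MovementCategory.X_TO_X
            truth_rows.append((g, src, dst, cat.value))
        # rebuild the focal table with moved genes relocated
        new_by_chrom: dict[str, list[str]] = {c: [] for c in chroms}
        for rec in focal_table.records:
            dest = moved.get(rec.gene_id, rec.chromosome)
            new_by_chrom[dest].append(rec.gene_id)
        records = []
        lengths_out: dict[str, int] = {}
        for chrom in chroms:
            recs = _lay_out_chromosome(new_by_chrom[chrom], elements, chrom, rng)
            records.extend(recs)
            end = max((r.end for r in recs), default=0)
            lengths_out[chrom] = max(end + 1000, lengths[chrom])
        focal_table = GeneMapTable("focal", records, lengths_out)

    if mismap_rate > 0 or unplaced_rate > 0:
        focal_table = _apply_noise(focal_table, elements, mismap_rate, unplaced_rate, rng)

    out1_table, _ = sim_gene_map(out1_spec, elements, mismap_rate, unplaced_rate, rng)
    out2_table, _ = sim_gene_map(out2_spec, elements, mismap_rate, unplaced_rate, rng)

    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "source", "destination", "category"]
    ).set_index("gene_id") if truth_rows else pd.DataFrame(
        columns=["source", "destination", "category"]
    )
    tables = {"focal": focal_table, "out1": out1_table, "out2": out2_table}
    return tables, focal_x, truth


def _apply_noise(
    table: GeneMapTable,
    elements: Mapping[str, str],
    mismap_rate: float,
    unplaced_rate: float,
    rng: np.random.Generator,
) -> GeneMapTable:
    chroms = sorted(c for c, p in table.placed.items() if p)
    reassigned: dict[str, str] = {}
    n_scaffold = 0
    for rec in table.records:
        draw = rng.random()
        if draw < unplaced_rate:
            reassigned[rec.gene_id] = f"scaffold_{n_scaffold}"
            n_scaffold += 1
        elif draw < unplaced_rate + mismap_rate and len(chroms) > 1:
            wrong = [c for c in chroms if c != rec.chromosome]
            reassigned[rec.gene_id] = wrong[int(rng.integers(len(wrong)))]
    if not reassigned:
        return table
    by_chrom: dict[str, list[str]] = {}
    for rec in table.records:
        by_chrom.setdefault(reassigned.get(rec.gene_id, rec.chromosome), []).append(rec.gene_id)
    records: list[HitRecord] = []
    lengths = dict(table.chromosome_lengths)
    placed = dict(table.placed)
    for chrom, genes in by_chrom.items():
        recs = _lay_out_chromosome(genes, elements, chrom, rng)
        records.extend(recs)
        end = max(r.end for r in recs) + 100
        if chrom in lengths:
            lengths[chrom] = max(lengths[chrom], end)
        else:
            lengths[chrom] = end
            placed[chrom] = False  # new scaffolds are unassembled
    return GeneMapTable(table.species_id, records, lengths, placed)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

DEFAULT_TISSUES = ("testis", "ovary", "head", "carcass")


def sim_expression(
    genes: Iterable[str],
    moved_out: Iterable[str],
    seed: int = 0,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    meanlog: float = 1.0,
    sdlog: float = 1.0,
    testis_multiplier: float = 2.0,
) -> pd.DataFrame:
    """Log-normal expression matrix with a planted testis effect.

    Genes in ``moved_out`` get their testis values multiplied by
    ``testis_multiplier``; somatic tissues are untouched (negative
    controls).
    """
    genes = sorted(set(genes))
    moved = set(moved_out)
    unknown = moved - set(genes)
    if unknown:
        raise ValueError(f"moved genes not in gene set: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    data = rng.lognormal(meanlog, sdlog, size=(len(genes), len(tissues)))
    df = pd.DataFrame(data, index=genes, columns=list(tissues))
    if "testis" in df.columns and moved:
        mask = df.index.isin(moved)
        df.loc[mask, "testis"] *= testis_multiplier
    df.index.name = "gene_id"
    return df
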