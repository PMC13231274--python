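"""Windowed GC content and X-vs-autosome comparison.

Chromosomes are cut into fixed windows (default 100 kb window and step);
``gc_fraction`` is (G+C)/(A+C+G+T), case-insensitive, with N and other
ambiguity codes excluded from the denominator.  Windows with fewer than
half their nominal size in unambiguous bases are computed but flagged and
left out of statistics (this also drops short trailing windows).  X and
autosomal windows are compared with a two-sided Mann–Whitney U test.

Windows on the same chromosome are not independent observations; the
comparison warns about this pseudoreplication and leaves the p-value
uncorrected.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

logger = logging.getLogger("mullerx")


@dataclass(frozen=True)
class GCWindow:
    chromosome: str
    start: int
    end: int
    gc_fraction: float | None  # None when no unambiguous bases
    n_valid: int
    included: bool  # passes the >=50% unambiguous-base rule


@dataclass
class GCComparison:
    u_statistic: float
    p: float
    median_x: float
    median_auto: float
    direction: str  # "X_higher", "X_lower", "ns"
    n_x: int
    n_auto: int


def _iter_fasta(path: str | Path):
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    name = None
    chunks: list[str] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            yield name, "".join(chunks)


_GC_BYTES = frozenset(b"GCgc")
_VALID_BYTES = frozenset(b"ACGTacgt")


def gc_windows(
    source: str | Path | Mapping[str, str],
    window: int = 100_000,
    step: int = 100_000,
    min_valid_frac: float = 0.5,
) -> list[GCWindow]:
    """GC fraction in sliding windows over a genome.

    ``source`` is a FASTA path (gzip-transparent) or an in-memory mapping
    of sequence name to sequence.  Windows start at offsets 0, step,
    2*step, ...; the trailing partial window is kept with its true length.
    A window is ``included`` when its unambiguous bases cover at least
    ``min_valid_frac`` of the nominal window size.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if isinstance(source, (str, Path)):
        seqs: Iterable[tuple[str, str]] = _iter_fasta(source)
    else:
        seqs = source.items()

    out: list[GCWindow] = []
    for name, seq in seqs:
        if not seq:
            logger.warning("empty sequence %s: no windows", name)
            continue
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_valid = is_gc | (arr == ord("A")) | (arr == ord("T"))
        cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
        cum_valid = np.concatenate([[0], np.cumsum(is_valid)])
        n = len(arr)
        for start in range(0, n, step):
            end = min(start + window, n)
            gc = int(cum_gc[end] - cum_gc[start])
            valid = int(cum_valid[end] - cum_valid[start])
            frac = gc / valid if valid > 0 else None
            out.append(
                GCWindow(
                    chromosome=name,
                    start=start,
                    end=end,
                    gc_fraction=frac,
                    n_valid=valid,
                    included=valid / window >= min_valid_frac,
                )
            )
    return out


def compare_gc_x_autosome(
    windows: Iterable[GCWindow],
    x_chromosomes: set[str],
    alpha: float = 0.05,
) -> GCComparison:
    """Mann–Whitney comparison of X vs autosomal window GC fractions."""
    x_vals: list[float] = []
    a_vals: list[float] = []
    for w in windows:
        if not w.included or w.gc_fraction is None:
            continue
        (x_vals if w.chromosome in x_chromosomes else a_vals).append(w.gc_fraction)
    if len(x_vals) < 2 or len(a_vals) < 2:
        raise ValueError(
            f"need at least 2 included windows per side (X: {len(x_vals)}, "
            f"autosomes: {len(a_vals)})"
        )
    logger.warning(
        "windows within a chromosome are not independent; the Mann-Whitney "
        "p-value is subject to pseudoreplication"
    )
    res = stats.mannwhitneyu(x_vals, a_vals, alternative="two-sided")
    med_x = float(np.median(x_vals))
    med_a = float(np.median(a_vals))
    if res.pvalue < alpha:
        direction = "X_higher" if med_x > med_a else "X_lower"
    else:
        direction = "ns"
    return GCComparison(
        u_statistic=float(res.statistic),
        p=float(res.pvalue),
        median_x=med_x,
        median_auto=med_a,
        direction=direction,
        n_x=len(x_vals),
        n_auto=len(a_vals),
    )


def write_windows_tsv(windows: Iterable[GCWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\tgc\tn_valid\tincluded\n")
        for w in windows:
            gc = f"{w.gc_fraction:.6f}" if w.gc_fraction is not None else "NA"
            fh.write(f"{w.chromosome}\t{w.start}\t{w.end}\t{gc}\t{w.n_valid}\t{int(w.included)}\n")
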