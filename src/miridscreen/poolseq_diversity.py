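"""Sliding-window nucleotide diversity and Tajima's D from pooled read counts.

The estimators are the classical Tajima quantities computed directly on read
counts: per covered site the heterozygosity

    pi_hat = 1 - sum_a C(c_a, 2) / C(M, 2)

over alleles a with read counts c_a at coverage M; Watterson's theta from the
count of SNP sites (minor allele count >= ``min_count``); and Tajima's D with
the standard constants evaluated at n = ``pool_n`` chromosomes.  This is an
approximation of pool-aware corrected estimators: read counts, not
chromosomes, are treated as the sample, so pi is shrunk by roughly
(n-1)/n relative to theta and the minor-allele-count filter truncates the
rare tail of the site-frequency spectrum (which biases D upward when the
filter removes true singleton-frequency alleles rather than sequencing
errors).  See the methods note for the quantitative effect.

Windows never extend past scaffold ends; with step = window the windows
partition the scaffold prefix of floor(L/window) * window bp and a trailing
remainder is reported as a short final window flagged partial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import SiteCounts
from .synthetic_data import PoolPileup, harmonic_number


@dataclass
class PoolParams:
    pool_n: int = 40
    window: int = 10_000
    step: int = 10_000
    min_count: int = 2
    min_cov: int = 4
    max_cov: int = 400
    min_covered_fraction: float = 0.60
    indel_flank: int = 5
    target_coverage: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_n < 2:
            raise ValueError("pool_n must be at least 2")
        if not (0 < self.min_covered_fraction <= 1):
            raise ValueError("min_covered_fraction must be in (0, 1]")
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be positive")


@dataclass
class WindowStat:
    scaffold_id: str
    start: int
    end: int
    covered_fraction: float
    n_covered: int
    n_snps: int
    pi: float            # NaN when insufficient
    tajimas_d: float     # NaN when insufficient or S = 0
    sufficient: bool
    partial: bool = False


@dataclass
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Standard constants of Tajima's D for a sample of n chromosomes."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


# ---------------------------------------------------------------------------
# input adaptation
# ---------------------------------------------------------------------------

def _as_pileup(sites: PoolPileup | Sequence[SiteCounts]) -> dict[str, PoolPileup]:
    """Group input into per-scaffold columnar pileups."""
    if isinstance(sites, PoolPileup):
        return {sites.scaffold_id: sites}
    grouped: dict[str, list[SiteCounts]] = {}
    for s in sites:
        grouped.setdefault(s.scaffold_id, []).append(s)
    out: dict[str, PoolPileup] = {}
    base_code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}
    for scaffold_id, rows in grouped.items():
        rows.sort(key=lambda s: s.pos)
        pos = np.array([s.pos for s in rows], dtype=np.int64)
        ref = np.array([base_code[s.ref] for s in rows], dtype=np.int8)
        counts = np.array(
            [[s.a, s.c, s.g, s.t] for s in rows], dtype=np.int32
        )
        indel = np.array([s.indel_events for s in rows], dtype=np.int16)
        masked = np.array([s.masked for s in rows], dtype=bool)
        out[scaffold_id] = PoolPileup(
            scaffold_id, pos, ref, counts, indel, masked=masked
        )
    return out


# ---------------------------------------------------------------------------
# subsampling and indel masking
# ---------------------------------------------------------------------------

def subsample_to_coverage(
    sites: PoolPileup | Sequence[SiteCounts],
    target_coverage: float,
    seed: int = 0,
) -> tuple[PoolPileup | list[SiteCounts], float]:
    """Thin per-site read counts without replacement to a target mean coverage.

    Each site keeps Binomial(M, target/current) reads; which alleles they
    carry is drawn hypergeometrically from the site's counts.  Deterministic
    under the seed.  Returns the thinned input (same shape as given) and the
    achieved mean coverage.
    """
    pileups = _as_pileup(sites)
    current = float(
        np.mean(np.concatenate([p.counts.sum(axis=1) for p in pileups.values()]))
    )
    if target_coverage > current:
        raise ValueError(
            f"target coverage {target_coverage} exceeds current {current:.2f}"
        )
    rate = target_coverage / current
    rng = np.random.default_rng(seed)
    achieved_total = 0
    achieved_sites = 0
    out: dict[str, PoolPileup] = {}
    for scaffold_id, p in sorted(pileups.items()):
        cov = p.counts.sum(axis=1)
        keep = rng.binomial(cov, rate)
        new_counts = np.zeros_like(p.counts)
        poly = (p.counts > 0).sum(axis=1) > 1
        mono = ~poly
        mono_allele = p.counts[mono].argmax(axis=1)
        new_counts[np.where(mono)[0], mono_allele] = keep[mono]
        for idx in np.where(poly)[0]:
            new_counts[idx] = rng.multivariate_hypergeometric(
                p.counts[idx], int(keep[idx])
            )
        achieved_total += int(new_counts.sum())
        achieved_sites += len(p.pos)
        out[scaffold_id] = PoolPileup(
            scaffold_id, p.pos.copy(), p.ref.copy(), new_counts,
            p.indel_events.copy(),
            masked=None if p.masked is None else p.masked.copy(),
        )
    achieved = achieved_total / max(achieved_sites, 1)
    if isinstance(sites, PoolPileup):
        return out[sites.scaffold_id], achieved
    result: list[SiteCounts] = []
    for scaffold_id, p in sorted(out.items()):
        result.extend(p.to_sites())
    return result, achieved


def mask_indels(
    sites: PoolPileup | Sequence[SiteCounts], indel_flank: int = 5
) -> PoolPileup | list[SiteCounts]:
    """Mask every position within +/- ``indel_flank`` of an indel-bearing site.

    Masked sites are excluded from coverage and SNP accounting downstream.
    Masking more sites never increases a window's covered fraction.
    """
    pileups = _as_pileup(sites)
    out: dict[str, PoolPileup] = {}
    for scaffold_id, p in sorted(pileups.items()):
        masked = np.zeros(len(p.pos), dtype=bool)
        if p.masked is not None:
            masked |= p.masked
        indel_pos = p.pos[p.indel_events > 0]
        if len(indel_pos):
            # positions are sorted; mark every site within the flank of any
            # indel position via interval search
            starts = indel_pos - indel_flank
            ends = indel_pos + indel_flank
            lo = np.searchsorted(p.pos, starts, side="left")
            hi = np.searchsorted(p.pos, ends, side="right")
            for a, b in zip(lo, hi):
                masked[a:b] = True
        out[scaffold_id] = PoolPileup(
            scaffold_id, p.pos, p.ref, p.counts, p.indel_events, masked=masked
        )
    if isinstance(sites, PoolPileup):
        return out[sites.scaffold_id]
    result: list[SiteCounts] = []
    for scaffold_id, p in sorted(out.items()):
        converted = p.to_sites()
        for s, flag in zip(converted, p.masked):
            s.masked = bool(flag)
        result.extend(converted)
    return result


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------

def _site_pi(counts: np.ndarray) -> np.ndarray:
    """Per-site heterozygosity 1 - sum_a C(c_a,2) / C(M,2), vectorized."""
    M = counts.sum(axis=1).astype(np.float64)
    same = (counts.astype(np.float64) * (counts - 1)).sum(axis=1)
    denom = M * (M - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 1.0 - same / denom
    pi[denom <= 0] = 0.0
    return pi


def window_stats(
    sites: PoolPileup | Sequence[SiteCounts],
    params: PoolParams | None = None,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[WindowStat]:
    """Per-window coverage sufficiency, S, pi and Tajima's D.

    A site is covered iff ``min_cov <= coverage <= max_cov`` and not masked;
    it is a SNP iff covered and its minor allele count (coverage minus the
    major allele's reads) is at least ``min_count``.  Window pi is the sum of
    per-site heterozygosities over SNP sites divided by the number of covered
    sites; Watterson's theta is S / (a1 x covered sites); D follows the
    classical variance with constants from ``pool_n``.  D is NaN when S = 0;
    windows below the covered-fraction threshold carry no pi/D values.
    """
    params = params or PoolParams()
    const = tajima_constants(params.pool_n)
    pileups = _as_pileup(sites)
    stats: list[WindowStat] = []
    for scaffold_id, p in sorted(pileups.items()):
        if len(p.pos) == 0:
            continue
        L = None
        if scaffold_lengths is not None:
            L = scaffold_lengths.get(scaffold_id)
        if L is None:
            L = int(p.pos.max()) + 1
        cov = p.counts.sum(axis=1)
        masked = p.masked if p.masked is not None else np.zeros(len(p.pos), bool)
        covered = (cov >= params.min_cov) & (cov <= params.max_cov) & ~masked
        major = p.counts.max(axis=1)
        minor = cov - major
        snp = covered & (minor >= params.min_count)
        pi_site = _site_pi(p.counts)

        starts = list(range(0, max(L - params.window + 1, 1), params.step))
        tail_start = starts[-1] + params.window if starts else 0
        windows = [(s, s + params.window, False) for s in starts]
        if tail_start < L:
            windows.append((tail_start, L, True))
        for ws, we, partial in windows:
            lo = int(np.searchsorted(p.pos, ws, side="left"))
            hi = int(np.searchsorted(p.pos, we, side="left"))
            sel_cov = covered[lo:hi]
            n_cov = int(sel_cov.sum())
            frac = n_cov / (we - ws)
            sel_snp = snp[lo:hi]
            S = int(sel_snp.sum())
            sufficient = frac >= params.min_covered_fraction
            if not sufficient or n_cov == 0:
                stats.append(
                    WindowStat(scaffold_id, ws, we, frac, n_cov, S,
                               math.nan, math.nan, sufficient, partial)
                )
                continue
            pi_sum = float(pi_site[lo:hi][sel_snp].sum())
            pi = pi_sum / n_cov
            if S == 0:
                d = math.nan
            else:
                theta_w_sum = S / const.a1
                var = const.e1 * S + const.e2 * S * (S - 1)
                d = (pi_sum - theta_w_sum) / math.sqrt(var) if var > 0 else math.nan
            stats.append(
                WindowStat(scaffold_id, ws, we, frac, n_cov, S, pi, d,
                           sufficient, partial)
            )
    return stats


def genome_summary(
    stats: Sequence[WindowStat],
) -> tuple[float, float, "pd.DataFrame"]:
    """Genome-wide pi and D (unweighted means over sufficient windows) plus a
    per-scaffold table (windows, sufficient windows, mean covered fraction of
    sufficient windows, mean pi, mean D).

    Windows with undefined D (S = 0) are excluded from D means.
    """
    import pandas as pd

    sufficient = [w for w in stats if w.sufficient]
    if not sufficient:
        raise ValueError("no sufficiently covered windows")
    pis = [w.pi for w in sufficient if not math.isnan(w.pi)]
    ds = [w.tajimas_d for w in sufficient if not math.isnan(w.tajimas_d)]
    genome_pi = float(np.mean(pis)) if pis else math.nan
    genome_d = float(np.mean(ds)) if ds else math.nan
    rows = []
    for scaffold_id in sorted({w.scaffold_id for w in stats}):
        scaffold_windows = [w for w in stats if w.scaffold_id == scaffold_id]
        suff = [w for w in scaffold_windows if w.sufficient]
        s_pis = [w.pi for w in suff if not math.isnan(w.pi)]
        s_ds = [w.tajimas_d for w in suff if not math.isnan(w.tajimas_d)]
        rows.append(
            {
                "scaffold": scaffold_id,
                "windows": len(scaffold_windows),
                "sufficient_windows": len(suff),
                "mean_covered_fraction": (
                    float(np.mean([w.covered_fraction for w in suff]))
                    if suff else math.nan
                ),
                "mean_pi": float(np.mean(s_pis)) if s_pis else math.nan,
                "mean_tajimas_d": float(np.mean(s_ds)) if s_ds else math.nan,
            }
        )
    return genome_pi, genome_d, pd.DataFrame(rows)
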