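"""Zipper statistics: ZH, the AUZ family, and permutation p-values.

ZH (Zipper Height) is the fraction of input features whose closest peak
overlaps the TSS.  AUZ (Area Under the Zipper) sums, over features, the area
between each TSS and its closest peak; with one unit of zipper height per
feature this is the sum of |distance|.  AUZ_left/right split the sum by the
side (upstream/downstream in feature orientation) on which the closest peak
was found; AUZ_window clips every distance at the visualization window
half-width so plots with the same window are directly comparable.

The one-sided AUZ p-value compares the observed AUZ to the AUZ of random TSS
sets drawn uniformly over the genome minus an exclusion set (assembly gaps,
centromeres, telomeres, heterochromatin, repeats), preserving the per
chromosome feature counts; p = #(AUZ_random <= AUZ_observed) / reps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .peakdb import PeakIndex
from .query import FeatureTSS, PeakHit, _distances, nearest_peak

__all__ = [
    "ZipperStats",
    "ExclusionSet",
    "RandomizationConfig",
    "zipper_height",
    "auz",
    "auz_window",
    "sample_random_tss",
    "auz_pvalue",
    "permutation_pvalues",
    "per_tss_tissue_pvalue",
    "compute_stats",
]

WINDOW_DEFAULT = 5_000
REPS_DEFAULT = 100


@dataclass
class ZipperStats:
    """The statistics block of one zipper run."""

    zh: float
    auz_global: float
    auz_left: float
    auz_right: float
    auz_window: float
    auz_window_left: float
    auz_window_right: float
    window_halfwidth: int = WINDOW_DEFAULT
    n_features: int = 0
    n_missing: int = 0
    auz_pval: float | None = None
    auz_left_pval: float | None = None
    auz_right_pval: float | None = None
    reps: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "ZH": self.zh,
            "AUZ_global": self.auz_global,
            "AUZ_left": self.auz_left,
            "AUZ_right": self.auz_right,
            "AUZ_window": self.auz_window,
            "AUZ_window_left": self.auz_window_left,
            "AUZ_window_right": self.auz_window_right,
            "window_halfwidth": self.window_halfwidth,
            "n_features": self.n_features,
            "n_missing": self.n_missing,
            "AUZ_pval": self.auz_pval,
            "AUZ_left_pval": self.auz_left_pval,
            "AUZ_right_pval": self.auz_right_pval,
            "reps": self.reps,
            "seed": self.seed,
        }


@dataclass
class RandomizationConfig:
    """Permutation-null settings: number of random zipper plots, RNG seed,
    and whether random TSSs copy the template's per-chromosome strand mix."""

    reps: int = REPS_DEFAULT
    seed: int = 0
    preserve_strand: bool = True
    pseudocount: bool = False  # (k+1)/(R+1) instead of the plain quotient

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


class ExclusionSet:
    """Merged disallowed intervals per chromosome (0-based half-open)."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        self._merged: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self._merged[chrom] = self._merge(ivs)

    @staticmethod
    def _merge(ivs: Sequence[tuple[int, int]]) -> np.ndarray:
        arr = sorted((int(s), int(e)) for s, e in ivs if int(e) > int(s))
        merged: list[list[int]] = []
        for s, e in arr:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return np.asarray(merged, dtype=np.int64).reshape(-1, 2)

    @classmethod
    def from_bed(cls, path: str | Path) -> "ExclusionSet":
        ivs: dict[str, list[tuple[int, int]]] = {}
        with open(path, "rt", encoding="utf-8") as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                ivs.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
        return cls(ivs)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._merged.get(chrom, np.empty((0, 2), dtype=np.int64))

    def contains(self, chrom: str, pos0: int) -> bool:
        """Is 0-based position ``pos0`` inside an excluded interval?"""
        ivs = self.intervals(chrom)
        if len(ivs) == 0:
            return False
        i = int(np.searchsorted(ivs[:, 0], pos0, side="right"))
        return i > 0 and pos0 < ivs[i - 1, 1]

    def allowed_intervals(self, chrom: str, length: int) -> np.ndarray:
        """Complement of the exclusion set on [0, length), as (start, end) rows."""
        out: list[tuple[int, int]] = []
        cursor = 0
        for s, e in self.intervals(chrom):
            s = max(0, min(int(s), length))
            e = max(0, min(int(e), length))
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < length:
            out.append((cursor, length))
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# core statistics


def zipper_height(hits: Sequence[PeakHit]) -> float:
    """Fraction of features whose closest peak overlaps the TSS.

    Missing hits count in the denominator (they certainly do not overlap).
    """
    if not hits:
        raise ValueError("zipper_height requires at least one hit")
    n_overlap = sum(1 for h in hits if h.distance == 0)
    return n_overlap / len(hits)


def auz(hits: Sequence[PeakHit]) -> tuple[float, float, float]:
    """(AUZ_global, AUZ_left, AUZ_right).

    Each non-missing hit contributes |distance| — a unit-height rectangle from
    the TSS to the nearest peak edge.  Left collects hits whose closest peak
    lies upstream (negative distance), right downstream (positive).  Missing
    hits contribute nothing here; they are reported via ``n_missing``.
    """
    if not hits:
        raise ValueError("auz requires at least one hit")
    left = float(sum(-h.distance for h in hits if h.distance is not None and h.distance < 0))
    right = float(sum(h.distance for h in hits if h.distance is not None and h.distance > 0))
    return left + right, left, right


def auz_window(
    hits: Sequence[PeakHit], w: int = WINDOW_DEFAULT
) -> tuple[float, float, float]:
    """(AUZ_window, AUZ_window_left, AUZ_window_right) at half-width ``w``.

    Distances beyond the window are clipped to ``w``; a missing hit (no peak
    anywhere on the chromosome) behaves like an infinitely far peak and
    contributes ``w``, split evenly between the two sides.
    """
    if w <= 0:
        raise ValueError("window half-width must be positive")
    if not hits:
        raise ValueError("auz_window requires at least one hit")
    left = right = 0.0
    for h in hits:
        if h.distance is None:
            left += w / 2
            right += w / 2
        elif h.distance < 0:
            left += min(-h.distance, w)
        elif h.distance > 0:
            right += min(h.distance, w)
    return left + right, left, right


def compute_stats(hits: Sequence[PeakHit], window: int = WINDOW_DEFAULT) -> ZipperStats:
    """Assemble the full statistics block (p-values left unset)."""
    g, l, r = auz(hits)
    gw, lw, rw = auz_window(hits, window)
    return ZipperStats(
        zh=zipper_height(hits),
        auz_global=g,
        auz_left=l,
        auz_right=r,
        auz_window=gw,
        auz_window_left=lw,
        auz_window_right=rw,
        window_halfwidth=window,
        n_features=len(hits),
        n_missing=sum(1 for h in hits if h.is_missing),
    )


# ---------------------------------------------------------------------------
# permutation null


def sample_random_tss(
    template: Sequence[FeatureTSS],
    chrom_sizes: Mapping[str, int],
    excl: ExclusionSet | None = None,
    seed: int | np.random.Generator = 0,
    preserve_strand: bool = True,
) -> list[FeatureTSS]:
    """Draw a random TSS set matching the template's per-chromosome counts.

    Positions are uniform over each chromosome minus the exclusion set
    (cumulative allowed-length inversion); strands copy the template's
    per-chromosome strand multiset when ``preserve_strand`` is on, else are
    drawn uniformly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excl = excl or ExclusionSet()
    by_chrom: dict[str, list[FeatureTSS]] = {}
    for t in template:
        by_chrom.setdefault(t.chrom, []).append(t)

    queues: dict[str, list[FeatureTSS]] = {}
    for chrom in sorted(by_chrom):
        feats = by_chrom[chrom]
        length = chrom_sizes.get(chrom)
        if length is None:
            raise ValueError(f"template chromosome {chrom!r} absent from chrom_sizes")
        allowed = excl.allowed_intervals(chrom, length)
        lens = allowed[:, 1] - allowed[:, 0]
        total = int(lens.sum())
        if total <= 0:
            raise ValueError(f"chromosome {chrom!r} is entirely excluded")
        cum = np.cumsum(lens)
        draws = rng.integers(0, total, size=len(feats))
        idx = np.searchsorted(cum, draws, side="right")
        offsets = draws - (cum[idx - 1] * (idx > 0))
        pos0 = allowed[idx, 0] + offsets
        if preserve_strand:
            strands = [f.strand for f in feats]
        else:
            strands = list(rng.choice(["+", "-"], size=len(feats)))
        queues[chrom] = [
            FeatureTSS(chrom, int(p) + 1, s, label=None)
            for p, s in zip(pos0, strands)
        ]

    out: list[FeatureTSS] = []
    for t in template:  # preserve template order
        out.append(queues[t.chrom].pop(0))
    return out


def _auz_from_distances(distances: Sequence[int | None]) -> tuple[float, float, float]:
    left = float(sum(-d for d in distances if d is not None and d < 0))
    right = float(sum(d for d in distances if d is not None and d > 0))
    return left + right, left, right


def permutation_pvalues(
    observed: tuple[float, float, float],
    features: Sequence[FeatureTSS],
    index: PeakIndex,
    sample_id: str | None = None,
    cfg: RandomizationConfig | None = None,
    excl: ExclusionSet | None = None,
) -> tuple[float, float, float]:
    """(p_global, p_left, p_right) from one set of random zipper plots.

    Each replicate draws a random TSS set (same per-chromosome counts,
    exclusion-aware), queries it in the same mode as the observed run, and
    computes its AUZ triple; each p-value is the fraction of replicates whose
    AUZ is <= the observed one (one-sided: small p means the observed zipper
    is tighter than random).
    """
    cfg = cfg or RandomizationConfig()
    rng = np.random.default_rng(cfg.seed)
    obs_g, obs_l, obs_r = observed
    k_g = k_l = k_r = 0
    for _ in range(cfg.reps):
        rand = sample_random_tss(
            features, index.chrom_sizes, excl, seed=rng, preserve_strand=cfg.preserve_strand
        )
        g, l, r = _auz_from_distances(_distances(rand, index, sample_id))
        k_g += g <= obs_g
        k_l += l <= obs_l
        k_r += r <= obs_r
    if cfg.pseudocount:
        denom = cfg.reps + 1
        return (k_g + 1) / denom, (k_l + 1) / denom, (k_r + 1) / denom
    return k_g / cfg.reps, k_l / cfg.reps, k_r / cfg.reps


def auz_pvalue(
    observed_auz: float,
    features: Sequence[FeatureTSS],
    index: PeakIndex,
    sample_id: str | None = None,
    cfg: RandomizationConfig | None = None,
    excl: ExclusionSet | None = None,
) -> float:
    """One-sided permutation p-value for AUZ_global (see
    :func:`permutation_pvalues`)."""
    p, _, _ = permutation_pvalues(
        (observed_auz, float("inf"), float("inf")), features, index, sample_id, cfg, excl
    )
    return p


def per_tss_tissue_pvalue(tss: FeatureTSS, index: PeakIndex, chosen_sample: str) -> float:
    """Fraction of samples with a peak as close (or closer) to the TSS than
    the chosen sample's peak.

    The chosen sample counts in its own numerator, so the minimum is
    1/#samples; samples with no eligible peak count as infinitely far.
    """
    if chosen_sample not in index.sample_ids:
        raise KeyError(f"unknown sample {chosen_sample!r}")

    def best_mag(sid: str) -> float:
        hit = nearest_peak(tss, index, sid)
        return float("inf") if hit.is_missing else abs(hit.distance)

    chosen = best_mag(chosen_sample)
    sids = index.sample_ids
    k = sum(1 for sid in sids if best_mag(sid) <= chosen)
    return k / len(sids)
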