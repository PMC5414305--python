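"""Model/Results objects tying the pipeline together.

:class:`ZipperModel` holds one analysis specification — a feature (TSS) set,
a peak index, the query mode and the window — and ``fit()`` runs the
queries, statistics and (optionally) the permutation null, returning a
:class:`ZipperResults` that carries the hits, the statistics block, a
summary table, and the plotting / report exporters.

:class:`StitchModel` does the same for the lncRNA 5'-boundary audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import plot as _plot
from . import report as _report
from .peakdb import PeakIndex
from .query import FeatureTSS, PeakHit, batch_query, read_features
from .stats import (
    ExclusionSet,
    RandomizationConfig,
    ZipperStats,
    auz,
    compute_stats,
    permutation_pvalues,
    per_tss_tissue_pvalue,
)
from .stitch import (
    CAGE_RADIUS_DEFAULT,
    MAX_GAP_DEFAULT,
    MIN_OVERLAP_DEFAULT,
    Junction,
    StitchCandidate,
    TranscriptModel,
    bin_support,
    junction_support,
    overlap_fraction_stats,
    select_unsupported,
    stitch_candidates,
)

__all__ = ["ZipperModel", "ZipperResults", "StitchModel", "StitchResults"]


class ZipperModel:
    """TSS-to-peak proximity analysis for one feature set and one assay.

    Parameters
    ----------
    features
        The stranded TSS positions under study.
    index
        The peak database for one assay.
    sample_id
        Query one sample, or ``None`` for the all-samples workflow (per
        feature, the sample with the closest peak is retained).
    window
        Zipper window half-width in nt (clipping bound for AUZ_window and the
        plot range).
    exclusions
        Genomic regions the permutation null may not sample from.
    """

    def __init__(
        self,
        features: Sequence[FeatureTSS],
        index: PeakIndex,
        sample_id: str | None = None,
        window: int = 5_000,
        exclusions: ExclusionSet | None = None,
    ) -> None:
        if not features:
            raise ValueError("ZipperModel requires a non-empty feature list")
        if sample_id is not None and sample_id not in index.sample_ids:
            raise KeyError(f"unknown sample_id {sample_id!r}")
        if window <= 0:
            raise ValueError("window must be positive")
        self.features = list(features)
        self.index = index
        self.sample_id = sample_id
        self.window = window
        self.exclusions = exclusions

    @classmethod
    def from_files(
        cls,
        features_path: str | Path,
        db_path: str | Path,
        sample_id: str | None = None,
        window: int = 5_000,
        exclusions_bed: str | Path | None = None,
        max_features: int = 20_000,
    ) -> "ZipperModel":
        """Build a model from the on-disk formats (feature TSV + database
        directory [+ exclusion BED])."""
        features = read_features(features_path, max_features=max_features)
        index = PeakIndex.from_dir(db_path)
        excl = ExclusionSet.from_bed(exclusions_bed) if exclusions_bed else None
        return cls(features, index, sample_id=sample_id, window=window, exclusions=excl)

    def fit(
        self,
        reps: int = 100,
        seed: int = 0,
        compute_pvalue: bool = True,
        tss_pvalues: bool = False,
    ) -> "ZipperResults":
        """Run the queries and statistics.

        ``reps`` random zipper plots feed the one-sided AUZ p-values;
        ``tss_pvalues`` additionally computes the per-TSS cross-tissue
        p-value (one-sample mode only).
        """
        hits = batch_query(self.features, self.index, self.sample_id)
        stats = compute_stats(hits, self.window)
        stats.seed = seed
        if compute_pvalue:
            cfg = RandomizationConfig(reps=reps, seed=seed)
            observed = auz(hits)
            p_g, p_l, p_r = permutation_pvalues(
                observed, self.features, self.index, self.sample_id, cfg, self.exclusions
            )
            stats.auz_pval, stats.auz_left_pval, stats.auz_right_pval = p_g, p_l, p_r
            stats.reps = reps
        tss_p: dict[str, float] | None = None
        if tss_pvalues:
            if self.sample_id is None:
                raise ValueError("per-TSS tissue p-values require one-sample mode")
            tss_p = {
                t.label: per_tss_tissue_pvalue(t, self.index, self.sample_id)
                for t in self.features
            }
        return ZipperResults(self, hits, stats, tss_p)


@dataclass
class ZipperResults:
    """Fit output: hits, statistics, and exporters."""

    model: ZipperModel
    hits: list[PeakHit]
    stats: ZipperStats
    tss_pvalues: dict[str, float] | None = None

    def summary_frame(self) -> pd.DataFrame:
        """The summary table (one row per feature, input order)."""
        return _report.summary_table(self.hits, self.tss_pvalues)

    def summary(self) -> str:
        """Plain-text statistics summary."""
        s = self.stats
        lines = [
            "Zipper analysis summary",
            "=======================",
            f"features            {s.n_features}",
            f"missing hits        {s.n_missing}",
            f"window half-width   {s.window_halfwidth} nt",
            f"ZH                  {s.zh:.4g}",
            f"AUZ_global          {s.auz_global:.4g}",
            f"AUZ_left            {s.auz_left:.4g}",
            f"AUZ_right           {s.auz_right:.4g}",
            f"AUZ_window          {s.auz_window:.4g}",
            f"AUZ_window_left     {s.auz_window_left:.4g}",
            f"AUZ_window_right    {s.auz_window_right:.4g}",
        ]
        if s.auz_pval is not None:
            lines += [
                f"AUZ_pval            {s.auz_pval:.4g}  ({s.reps} reps, seed {s.seed})",
                f"AUZ_left_pval       {s.auz_left_pval:.4g}",
                f"AUZ_right_pval      {s.auz_right_pval:.4g}",
            ]
        else:
            lines.append("AUZ_pval            not computed")
        return "\n".join(lines)

    def geometry(self) -> _plot.ZipperGeometry:
        ranked = _plot.rank_hits(self.hits)
        return _plot.build_geometry(ranked, self.model.window)

    def plot(self, path: str | Path, fmt: str | None = None) -> Path:
        """Render the zipper plot (SVG or PNG by extension)."""
        return _plot.render(self.geometry(), self.stats, path, fmt)

    def to_html(
        self,
        out: str | Path,
        plot_path: str | Path | None = None,
        title: str = "Zipper report",
        provenance: Mapping[str, object] | None = None,
    ) -> Path:
        """Write the self-contained HTML report (renders the plot if needed)."""
        out = Path(out)
        if plot_path is None:
            plot_path = out.with_suffix(".svg")
            self.plot(plot_path)
        return _report.html_report(
            plot_path, self.stats, self.summary_frame(), out, title=title,
            provenance=provenance,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        return _report.stats_json(self.stats, path)


class StitchModel:
    """The lncRNA 5'-boundary audit as a fittable model.

    Selects CAGE-unsupported lncRNAs, stitches them to upstream same-strand
    protein-coding genes within ``max_gap`` nt, and scores each stitch with
    junction-read evidence.
    """

    def __init__(
        self,
        lncrnas: Sequence[TranscriptModel],
        genes: Sequence[TranscriptModel],
        cage_index: PeakIndex,
        junctions: Sequence[Junction],
        radius: int = CAGE_RADIUS_DEFAULT,
        max_gap: int = MAX_GAP_DEFAULT,
        min_overlap: int = MIN_OVERLAP_DEFAULT,
    ) -> None:
        self.lncrnas = list(lncrnas)
        self.genes = list(genes)
        self.cage_index = cage_index
        self.junctions = list(junctions)
        self.radius = radius
        self.max_gap = max_gap
        self.min_overlap = min_overlap

    def fit(self) -> "StitchResults":
        unsupported = select_unsupported(self.lncrnas, self.cage_index, self.radius)
        cands = stitch_candidates(unsupported, self.genes, self.max_gap)
        scored = [
            junction_support(
                c, self.junctions, self.lncrnas, self.min_overlap, gene_universe=self.genes
            )
            for c in cands
        ]
        return StitchResults(self, unsupported, scored)


@dataclass
class StitchResults:
    model: StitchModel
    unsupported_lncrnas: list[TranscriptModel]
    candidates: list[StitchCandidate]

    @property
    def supported(self) -> list[StitchCandidate]:
        """Candidates with at least one retained junction read."""
        return [c for c in self.candidates if c.total_junction_reads >= 1]

    def candidate_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lncrna": c.lncrna.transcript_id,
                "gene": c.gene.transcript_id,
                "chrom": c.lncrna.chrom,
                "strand": c.lncrna.strand,
                "biotype_class": "mono-exonic" if c.lncrna.mono_exonic else "multi-exonic",
                "gap": c.gap,
                "n_junctions": len(c.supporting_junctions),
                "junction_reads": c.total_junction_reads,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(
            rows,
            columns=["lncrna", "gene", "chrom", "strand", "biotype_class", "gap",
                     "n_junctions", "junction_reads"],
        )

    def support_table(self) -> pd.DataFrame:
        """Junction-read bin counts per biotype class (each lncRNA once)."""
        return bin_support(self.candidates)

    def overlap_fractions(self) -> tuple[float, float]:
        return overlap_fraction_stats(self.candidates)

    def summary(self) -> str:
        table = self.support_table()
        lines = [
            "lncRNA 5'-boundary audit",
            "========================",
            f"lncRNAs supplied          {len(self.model.lncrnas)}",
            f"CAGE-unsupported          {len(self.unsupported_lncrnas)} "
            f"(no peak within {self.model.radius} nt)",
            f"stitched candidates       {len(self.candidates)} "
            f"(gap <= {self.model.max_gap} nt)",
            f"with junction support     {len(self.supported)}",
            "",
            table.to_string(),
        ]
        return "\n".join(lines)
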