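"""Satellite and rDNA repeat content from normalized read depth.

Mean read depth over labelled satellite regions of a mini-reference serves
as a proxy for genomic repeat content. Depths are normalized to the mean of
the sample (unweighted mean over mini-reference regions by default; a
region-length-weighted mean is available) and mutant/wild-type comparisons
are expressed as per-region log2 ratios, summarized per satellite class and
tested with Wilcoxon matched-pairs signed-rank tests.

Because each sample is normalized to its own mean, genuine expansions and
contractions shift that mean, displacing every ratio by a shared
compositional constant. ``class_log2_ratio`` therefore offers optional
median-centering of the per-region ratios (the usual copy-number assumption
that most regions are unaltered); raw ratios are the default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import FeatureTrack
from .errors import InputError
from . import stats as _stats

DEPTH_COLUMNS = ["sample", "region_id", "chrom", "start", "end", "class", "mean_depth"]


def mean_region_depth(per_base_depth: pd.DataFrame, regions: FeatureTrack,
                      sample_id: str = "sample") -> pd.DataFrame:
    """Coverage-weighted mean depth per region from bedGraph-like intervals.

    Depth intervals must be sorted and non-overlapping per chromosome; bases
    absent from the depth input count as depth 0. Regions on chromosomes
    absent from the depth input get mean 0 with a warning.
    """
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("start") for c, g in per_base_depth.groupby("chrom")
    } if len(per_base_depth) else {}
    for chrom, g in by_chrom.items():
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise InputError(f"overlapping depth intervals on {chrom}")
    missing_chroms = set()
    rows = []
    for i, (chrom, start, end, label) in enumerate(regions.intervals):
        g = by_chrom.get(chrom)
        if g is None:
            missing_chroms.add(chrom)
            rows.append((sample_id, f"r{i:05d}", chrom, start, end, label, 0.0))
            continue
        s = np.maximum(g["start"].to_numpy(), start)
        e = np.minimum(g["end"].to_numpy(), end)
        w = np.clip(e - s, 0, None)
        total = float((w * g["depth"].to_numpy()).sum())
        rows.append((sample_id, f"r{i:05d}", chrom, start, end, label,
                     total / (end - start)))
    if missing_chroms:
        warnings.warn(
            f"no depth data for chromosomes {sorted(missing_chroms)}; mean 0")
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS)


def normalize_to_sample_mean(table: pd.DataFrame,
                             length_weighted: bool = False) -> pd.DataFrame:
    """Divide every region's depth by the sample mean depth.

    The denominator is the unweighted mean over mini-reference regions
    (``length_weighted=True`` weights by region length instead). The mean of
    the normalized values is 1 by construction; normalizing an already
    normalized table is a no-op.
    """
    depths = table["mean_depth"].to_numpy(dtype=float)
    if not (depths > 0).any():
        raise InputError("all-zero depth table cannot be normalized")
    if length_weighted:
        w = (table["end"] - table["start"]).to_numpy(dtype=float)
        denom = float((depths * w).sum() / w.sum())
    else:
        denom = float(depths.mean())
    out = table.copy()
    out["normalized_depth"] = depths / denom
    return out


def class_log2_ratio(mutant: pd.DataFrame, wt: pd.DataFrame,
                     center: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region and per-class log2 ratios of mutant vs wild-type depth.

    Both tables must be normalized and share region ids. Regions with zero
    wild-type normalized depth are excluded with a warning. ``center`` may
    be ``"median"`` to subtract the median per-region ratio (compositional
    correction; assumes most regions unaltered). Ratios are antisymmetric
    under swapping the samples, with or without centering.
    """
    for t, who in ((mutant, "mutant"), (wt, "wt")):
        if "normalized_depth" not in t.columns:
            raise InputError(f"{who} table is not normalized")
    merged = mutant.merge(wt, on=["region_id", "class"], suffixes=("_mut", "_wt"))
    if len(merged) == 0:
        raise InputError("tables share no region ids")
    zero = merged["normalized_depth_wt"] <= 0
    excluded = int(zero.sum())
    if excluded:
        warnings.warn(f"excluded {excluded} regions with zero WT depth")
    merged = merged[~zero].copy()
    bad_mut = merged["normalized_depth_mut"] <= 0
    if bad_mut.any():
        warnings.warn(f"excluded {int(bad_mut.sum())} regions with zero mutant depth")
        merged = merged[~bad_mut].copy()
    merged["log2_ratio"] = np.log2(
        merged["normalized_depth_mut"] / merged["normalized_depth_wt"])
    if center == "median":
        merged["log2_ratio"] -= merged["log2_ratio"].median()
    elif center is not None:
        raise InputError(f"unknown centering mode {center!r}")
    per_region = merged[["region_id", "class", "log2_ratio"]].copy()
    per_class = (per_region.groupby("class", as_index=False)
                 .agg(mean_log2_ratio=("log2_ratio", "mean"),
                      n_regions=("log2_ratio", "size")))
    per_class.attrs["excluded_regions"] = excluded
    return per_region, per_class


def paired_class_test(mutant: pd.DataFrame, wt: pd.DataFrame,
                      satellite_class: str, min_pairs: int = 5) -> float | None:
    """Wilcoxon matched-pairs signed-rank p on normalized depths of one
    satellite class; ``None`` (indeterminate) with fewer than ``min_pairs``
    shared regions."""
    m = mutant[mutant["class"] == satellite_class]
    w = wt[wt["class"] == satellite_class]
    merged = m.merge(w, on="region_id", suffixes=("_mut", "_wt"))
    if len(merged) < min_pairs:
        warnings.warn(
            f"only {len(merged)} shared {satellite_class} regions; indeterminate")
        return None
    return _stats.wilcoxon_signed_rank(
        merged["normalized_depth_mut"].to_numpy(),
        merged["normalized_depth_wt"].to_numpy())


def regions_from_track(track: FeatureTrack,
                       allowed_classes=None) -> FeatureTrack:
    """Filter a BED-derived track to the satellite class vocabulary."""
    from .simulate import SATELLITE_CLASSES

    allowed = set(allowed_classes or SATELLITE_CLASSES)
    kept = [iv for iv in track.intervals if iv[3] in allowed]
    return FeatureTrack(name=track.name, intervals=kept)
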