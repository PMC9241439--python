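"""Crisis-induced genome instability analyses on WGS-derived tables.

Copy-number (CN) profiles are binned log2 ratios; crisis-specific changes
are isolated by subtracting a reference profile (parental from early
crisis, late from early) on an identical bin grid. Segments are maximal
runs of consecutive bins beyond a threshold with consistent sign; a segment
is *unique* to a sample when no other sample carries a same-direction
segment with sufficient reciprocal overlap. Structural variant (SV)
breakpoints are intersected with genomic fusion junctions over increasing
distance intervals, and clonality is classified from the median unique
variant allele frequency (VAF): a median well below 0.5 indicates a
polyclonal population (each subclone's private heterozygous variants are
carried by only a fraction of cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

CN_COLUMNS = ["chrom", "start", "end", "log2_ratio"]


# -------------------------------------------------------------- CNV profiles

def background_subtract(target: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-bin difference of log2 ratios; the bin grids must be identical."""
    for df in (target, reference):
        missing = set(CN_COLUMNS) - set(df.columns)
        if missing:
            raise InputError(f"CN profile missing columns {sorted(missing)}")
    t = target.reset_index(drop=True)
    r = reference.reset_index(drop=True)
    if len(t) != len(r) or not (
            t[["chrom", "start", "end"]].values == r[["chrom", "start", "end"]].values).all():
        raise InputError("bin grids differ; refusing to re-bin silently")
    out = t.copy()
    out["log2_ratio"] = t["log2_ratio"].to_numpy() - r["log2_ratio"].to_numpy()
    return out


def segment_profile(profile: pd.DataFrame, threshold: float,
                    min_bins: int) -> pd.DataFrame:
    """Maximal runs of >= min_bins consecutive bins with |log2| >= threshold
    and consistent sign become gain/loss segments."""
    if threshold <= 0 or min_bins < 1:
        raise InputError("threshold must be positive and min_bins >= 1")
    segs = []
    run: list[tuple] = []
    run_sign = 0

    def flush():
        if len(run) >= min_bins:
            chrom = run[0][0]
            values = [v for *_ignored, v in run]
            segs.append({
                "chrom": chrom, "start": run[0][1], "end": run[-1][2],
                "direction": "gain" if run_sign > 0 else "loss",
                "mean_log2": float(np.mean(values)), "n_bins": len(run),
            })

    prev_chrom = None
    for row in profile.itertuples(index=False):
        v = row.log2_ratio
        sign = 1 if v >= threshold else (-1 if v <= -threshold else 0)
        contiguous = (row.chrom == prev_chrom and run and run[-1][2] == row.start)
        if sign == 0 or sign != run_sign or not contiguous:
            flush()
            run, run_sign = [], sign
        if sign != 0:
            run.append((row.chrom, row.start, row.end, v))
            run_sign = sign
        prev_chrom = row.chrom
    flush()
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "direction",
                                       "mean_log2", "n_bins"])


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def unique_segments(cohort: dict[str, pd.DataFrame],
                    reciprocal_overlap: float = 0.5) -> dict[str, pd.DataFrame]:
    """Per-sample segments not shared (same direction, reciprocal overlap >=
    cutoff) with any other sample. Symmetric in sample order and idempotent."""
    if not 0 < reciprocal_overlap <= 1:
        raise InputError("reciprocal_overlap must lie in (0, 1]")
    out = {}
    for sample, segs in cohort.items():
        keep = []
        for seg in segs.itertuples(index=False):
            shared = False
            for other, osegs in cohort.items():
                if other == sample:
                    continue
                for oseg in osegs.itertuples(index=False):
                    if (oseg.chrom == seg.chrom and oseg.direction == seg.direction
                            and _reciprocal_overlap(seg.start, seg.end,
                                                    oseg.start, oseg.end)
                            >= reciprocal_overlap):
                        shared = True
                        break
                if shared:
                    break
            if not shared:
                keep.append(seg._asdict())
        out[sample] = pd.DataFrame(keep, columns=list(segs.columns))
    return out


# ------------------------------------------------------------- SV intersection

DEFAULT_DISTANCE_BINS_BP = (100_000, 1_000_000, 5_000_000, 10_000_000)


def sv_fusion_proximity(svs: pd.DataFrame, junction_positions,
                        distance_bins_bp=DEFAULT_DISTANCE_BINS_BP,
                        unique_only: bool = True) -> pd.DataFrame:
    """Fraction of fusion junctions within each distance of an SV breakpoint.

    SV table columns: sv_id, type, chrom1, pos1, chrom2, pos2, unique.
    Both breakpoints of every record (translocations included) enter the
    search independently; distance is same-chromosome only. Fractions are
    monotone non-decreasing over the bins.
    """
    bins = list(distance_bins_bp)
    if bins != sorted(bins) or len(set(bins)) != len(bins):
        raise InputError("distance bins must be strictly increasing")
    use = svs[svs["unique"].astype(bool)] if unique_only and len(svs) else svs
    bp_by_chrom: dict[str, list[int]] = {}
    for row in use.itertuples(index=False):
        bp_by_chrom.setdefault(str(row.chrom1), []).append(int(row.pos1))
        bp_by_chrom.setdefault(str(row.chrom2), []).append(int(row.pos2))
    for v in bp_by_chrom.values():
        v.sort()
    junctions = list(junction_positions)
    n = len(junctions)
    nearest = []
    for chrom, pos in junctions:
        cand = bp_by_chrom.get(chrom)
        if not cand:
            nearest.append(np.inf)
            continue
        i = np.searchsorted(cand, pos)
        best = np.inf
        if i < len(cand):
            best = min(best, abs(cand[i] - pos))
        if i > 0:
            best = min(best, abs(cand[i - 1] - pos))
        nearest.append(best)
    nearest = np.asarray(nearest, dtype=float)
    rows = [{"distance_bp": d,
             "fraction": float((nearest <= d).sum() / n) if n else 0.0,
             "n_junctions": n}
            for d in bins]
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ clonality

@dataclass
class ClonalityCall:
    sample_id: str
    median_vaf: float
    n_variants: int
    verdict: str  # 'monoclonal' | 'polyclonal' | 'indeterminate'
    threshold: float


def classify_clonality(vaf_table: pd.DataFrame, median_threshold: float = 0.4,
                       min_variants: int = 20) -> ClonalityCall:
    """Polyclonal iff the median unique-variant VAF falls below the
    threshold; indeterminate below the variant-count floor."""
    if not 0 < median_threshold < 0.5:
        raise InputError("median_threshold must lie in (0, 0.5)")
    sample = str(vaf_table["sample"].iloc[0]) if len(vaf_table) else ""
    vafs = vaf_table["vaf"].to_numpy(dtype=float)
    med = float(np.median(vafs)) if len(vafs) else np.nan
    if len(vafs) < min_variants:
        warnings.warn(f"only {len(vafs)} variants (< {min_variants}); "
                      "clonality indeterminate")
        return ClonalityCall(sample, med, len(vafs), "indeterminate",
                             median_threshold)
    verdict = "polyclonal" if med < median_threshold else "monoclonal"
    return ClonalityCall(sample, med, len(vafs), verdict, median_threshold)
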