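"""Fusion frequencies, junction summaries and comparative statistics.

Fusion frequency follows the fusion-PCR accounting: amplicon count divided
by the number of diploid genome equivalents in the DNA input (6.6 pg per
diploid human genome by default), expressed per diploid genome. Group
comparisons use the tests standard for this assay family: Fisher's exact
test on junction-chemistry contingencies, chi-squared with Yates'
correction against large simulated null sets, Mann-Whitney U for unpaired
group values, Wilcoxon signed-rank for matched pairs, Welch's t for growth
slopes, and exact binomial tests of per-chromosome fusion counts against
chromosome-size expectations.

Exact small-sample paths for Mann-Whitney and Wilcoxon are implemented by
full enumeration (scipy's exact methods decline ties); large samples use
scipy's tie-corrected normal approximations. Standard tests (Fisher,
Yates-corrected chi-squared, exact binomial, Welch) delegate to scipy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FeatureTrack
from .errors import DataError, InputError

PG_PER_DIPLOID_GENOME = 6.6


# ------------------------------------------------------------------ frequency

@dataclass
class FusionFrequency:
    sample_id: str
    amplicon_count: int
    dna_input_ng: float
    pg_per_diploid_genome: float
    frequency_per_diploid_genome: float


def fusion_frequency(amplicon_count: int, dna_input_ng: float,
                     pg_per_diploid_genome: float = PG_PER_DIPLOID_GENOME,
                     sample_id: str = "") -> FusionFrequency:
    """Fusion frequency per diploid genome.

    ``dna_input_ng * 1000 / pg_per_diploid_genome`` is the number of diploid
    genome equivalents assayed; the frequency is amplicons per equivalent.
    """
    if dna_input_ng <= 0:
        raise InputError("DNA input must be positive")
    if amplicon_count < 0:
        raise InputError("amplicon count cannot be negative")
    if pg_per_diploid_genome <= 0:
        raise InputError("pg_per_diploid_genome must be positive")
    genomes = dna_input_ng * 1000.0 / pg_per_diploid_genome
    return FusionFrequency(sample_id, amplicon_count, dna_input_ng,
                           pg_per_diploid_genome, amplicon_count / genomes)


def maximal_fusion_frequency(timecourse: pd.DataFrame,
                             pg_per_diploid_genome: float = PG_PER_DIPLOID_GENOME
                             ) -> pd.DataFrame:
    """Maximal frequency over sampled time points, per sample.

    ``timecourse`` columns: sample, timepoint, amplicon_count, dna_input_ng.
    """
    rows = []
    for sample, grp in timecourse.groupby("sample"):
        freqs = [fusion_frequency(int(r.amplicon_count), float(r.dna_input_ng),
                                  pg_per_diploid_genome).frequency_per_diploid_genome
                 for r in grp.itertuples(index=False)]
        rows.append((sample, max(freqs)))
    return pd.DataFrame(rows, columns=["sample", "max_frequency_per_diploid_genome"])


# ------------------------------------------------------- class / junction mix

def class_proportions(calls: pd.DataFrame) -> pd.DataFrame:
    """Proportions of resolved calls per fusion class (with counts)."""
    resolved = calls[calls["fusion_class"].isin(["intra", "inter", "genomic"])]
    if len(resolved) == 0:
        raise InputError("no resolved calls")
    counts = resolved["fusion_class"].value_counts()
    total = int(counts.sum())
    rows = [(c, int(counts.get(c, 0)), counts.get(c, 0) / total)
            for c in ("genomic", "inter", "intra")]
    return pd.DataFrame(rows, columns=["fusion_class", "count", "proportion"])


def _mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """t-based confidence interval on a mean."""
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    if len(values) < 2:
        return m, np.nan, np.nan
    half = sps.t.ppf(1 - (1 - level) / 2, len(values) - 1) * sps.sem(values)
    return m, m - half, m + half


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1 - level
    lo = sps.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = sps.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def summarize_junctions(calls: pd.DataFrame, group_id: str = "") -> pd.DataFrame:
    """Per-class junction chemistry summary.

    For each fusion class with at least one resolved call: MH / INS / blunt
    proportions (summing to 1), mean MH and INS lengths with 95% t-CIs, and
    the templated fraction among insertions. Classes without calls are
    omitted with a warning rather than fabricated.
    """
    rows = []
    for cls in ("genomic", "inter", "intra"):
        sub = calls[calls["fusion_class"] == cls]
        if len(sub) == 0:
            warnings.warn(f"no resolved calls in class {cls}; omitted")
            continue
        has_ins = sub["ins_seq"].fillna(".").ne(".") & sub["ins_seq"].notna()
        is_mh = sub["mh_len"] > 0
        is_blunt = ~is_mh & ~has_ins
        n = len(sub)
        mh_lens = sub.loc[is_mh, "mh_len"].to_numpy(dtype=float)
        ins_lens = sub.loc[has_ins, "ins_seq"].str.len().to_numpy(dtype=float)
        templated = sub.loc[has_ins, "ins_templated"].astype("boolean")
        mh_mean, mh_lo, mh_hi = _mean_ci(mh_lens) if len(mh_lens) else (np.nan,) * 3
        ins_mean, ins_lo, ins_hi = _mean_ci(ins_lens) if len(ins_lens) else (np.nan,) * 3
        rows.append({
            "group": group_id, "fusion_class": cls, "n": n,
            "prop_mh": is_mh.sum() / n, "prop_ins": has_ins.sum() / n,
            "prop_blunt": is_blunt.sum() / n,
            "mh_mean_bp": mh_mean, "mh_ci_lo": mh_lo, "mh_ci_hi": mh_hi,
            "ins_mean_bp": ins_mean, "ins_ci_lo": ins_lo, "ins_ci_hi": ins_hi,
            "templated_fraction": (float(templated.sum() / len(templated))
                                   if len(templated) else np.nan),
        })
    if not rows:
        raise InputError("no resolved calls in any class")
    return pd.DataFrame(rows)


# ----------------------------------------------------------- contingency tests

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (sum of hypergeometric
    probabilities no greater than the observed table's)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise InputError("table must be 2x2 and non-negative")
    margins = [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]
    if min(margins) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi_squared_yates(table) -> tuple[float, float]:
    """Continuity-corrected chi-squared statistic and p (1 df) for a 2x2."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise InputError("table must be 2x2 and non-negative")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    if (expected <= 0).any():
        raise InputError("zero expected cell")
    stat, p, _, _ = sps.chi2_contingency(t, correction=True)
    return float(stat), float(p)


def mann_whitney_u(x, y) -> float:
    """Two-sided Mann-Whitney U p: exhaustive enumeration of group
    assignments for combined n <= 20 (ties handled by working on the actual
    values), tie-corrected normal approximation otherwise."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise InputError("each group needs >= 3 observations")
    n1, n2 = len(x), len(y)
    if n1 + n2 <= 20:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        mu = n1 * n2 / 2.0

        def u_of(idx: tuple[int, ...]) -> float:
            r1 = ranks[list(idx)].sum()
            return r1 - n1 * (n1 + 1) / 2.0

        obs = abs(u_of(tuple(range(n1))) - mu)
        count = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            total += 1
            if abs(u_of(idx) - mu) >= obs - 1e-12:
                count += 1
        return count / total
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue)


def wilcoxon_signed_rank(pairs_or_diffs, other=None) -> float:
    """Two-sided Wilcoxon signed-rank p on paired data.

    Accepts either an array of differences or two paired arrays. Zero
    differences are dropped (count reported via warning). Exact enumeration
    of sign patterns for n <= 15, normal approximation otherwise.
    """
    d = np.asarray(list(pairs_or_diffs), dtype=float)
    if other is not None:
        d = d - np.asarray(list(other), dtype=float)
    nonzero = d[d != 0]
    dropped = len(d) - len(nonzero)
    if dropped:
        warnings.warn(f"dropped {dropped} zero differences")
    if len(nonzero) == 0:
        warnings.warn("all differences zero; degenerate test, p = 1")
        return 1.0
    if len(nonzero) < 5:
        raise InputError("need >= 5 non-zero differences")
    n = len(nonzero)
    if n <= 15:
        ranks = sps.rankdata(np.abs(nonzero))
        mu = ranks.sum() / 2.0
        w_obs = ranks[nonzero > 0].sum()
        obs = abs(w_obs - mu)
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if abs(w - mu) >= obs - 1e-12:
                count += 1
        return count / 2 ** n
    return float(sps.wilcoxon(nonzero, alternative="two-sided",
                              zero_method="wilcox", method="approx").pvalue)


def binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p (sum of outcome probabilities no greater
    than the observed outcome's), mirroring the Fisher convention."""
    return float(sps.binomtest(k, n, p, alternative="two-sided").pvalue)


# ------------------------------------------------------------------ enrichment

def chromosome_enrichment(junction_positions, chrom_lengths: dict[str, int]
                          ) -> pd.DataFrame:
    """Per-chromosome fusion enrichment against chromosome-size expectation.

    Expected count per chromosome is total x length share; each chromosome
    gets a two-sided exact binomial test of its observed count. Holm-adjusted
    p-values are reported alongside the raw ones (raw p drives comparisons).
    """
    from statsmodels.stats.multitest import multipletests

    positions = list(junction_positions)
    if not positions:
        raise InputError("need at least one junction")
    for chrom, _pos in positions:
        if chrom not in chrom_lengths:
            raise DataError(f"junction on unknown chromosome {chrom}")
    total = len(positions)
    genome = float(sum(chrom_lengths.values()))
    counts = pd.Series([c for c, _ in positions]).value_counts()
    rows = []
    for chrom, length in chrom_lengths.items():
        share = length / genome
        obs = int(counts.get(chrom, 0))
        rows.append({
            "chrom": chrom, "observed": obs, "expected": total * share,
            "p_value": binom_two_sided(obs, total, share),
            "test_name": "exact_binomial_two_sided",
        })
    df = pd.DataFrame(rows)
    df["p_holm"] = multipletests(df["p_value"], method="holm")[1]
    return df


def feature_coincidence(junction_positions, track: FeatureTrack) -> pd.DataFrame:
    """Count junctions coinciding with track intervals (0-based half-open).

    Returns one row per label plus an ``any`` row with the overall coincident
    count and proportion.
    """
    positions = list(junction_positions)
    n = len(positions)
    label_counts: dict[str, int] = {}
    any_count = 0
    for chrom, pos in positions:
        labels = set(track.labels_at(chrom, pos))
        if labels:
            any_count += 1
        for lab in labels:
            label_counts[lab] = label_counts.get(lab, 0) + 1
    rows = [{"label": "any", "coincident": any_count,
             "proportion": any_count / n if n else 0.0}]
    for lab in sorted(label_counts):
        rows.append({"label": lab, "coincident": label_counts[lab],
                     "proportion": label_counts[lab] / n})
    return pd.DataFrame(rows)


def compare_coincidence(k1: int, n1: int, k2: int, n2: int,
                        large_threshold: int = 1000) -> dict:
    """Compare coincident proportions of two groups.

    Fisher's exact test by default; a chi-squared test with Yates'
    correction when either group is a large simulated set (n above
    ``large_threshold``).
    """
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if max(n1, n2) > large_threshold:
        stat, p = chi_squared_yates(table)
        return {"test_name": "chi_squared_yates", "statistic": stat, "p_value": p}
    return {"test_name": "fisher_exact", "statistic": np.nan,
            "p_value": fisher_exact_2x2(table)}


# --------------------------------------------------------------------- growth

def ols_slope(time_days, values) -> float:
    """Ordinary least squares slope (population doublings per day)."""
    t = np.asarray(list(time_days), dtype=float)
    y = np.asarray(list(values), dtype=float)
    if len(t) < 3 or len(t) != len(y):
        raise InputError("need >= 3 matched time points")
    if np.ptp(t) == 0:
        raise InputError("degenerate time vector")
    tc = t - t.mean()
    return float((tc * (y - y.mean())).sum() / (tc ** 2).sum())


def growth_divergence(clone: pd.DataFrame, control: pd.DataFrame) -> float:
    """Slope differential (control slope minus clone slope): the degree of
    crisis-induced growth deceleration relative to the control."""
    s_clone = ols_slope(clone["day"], clone["pd"])
    s_control = ols_slope(control["day"], control["pd"])
    return s_control - s_clone


def compare_growth_divergence(group1, group2) -> float:
    """Welch's unequal-variance t-test on two groups of slope differentials."""
    a = np.asarray(list(group1), dtype=float)
    b = np.asarray(list(group2), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs >= 2 differentials")
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
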