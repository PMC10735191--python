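"""Ecological enrichment screen over trait counts and signal statistics.

A trait (a gene cluster class, cluster family, chitinase class, or
mycoparasitism orthogroup count) is a *candidate* for association with a
focal ecology when it simultaneously (i) shows weak phylogenetic signal
(K or lambda <= 0.8), (ii) is not significantly consistent with Brownian
motion (signal p > alpha), and (iii) is at least 2-fold enriched in the
focal group (E:NE or M:S ratio > 2). Flags are reported per metric (K and
lambda separately); a parallel D-based flag (D > 1 with the Brownian-null
p <= alpha) is reported alongside but not folded into ``flagged_any``.

Group comparisons use two-sample t or Wilcoxon rank-sum tests with Holm
step-down adjustment across the trait set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mgc_ecoscreen")


@dataclass(frozen=True)
class ScreenThresholds:
    signal_cutoff: float = 0.8
    alpha: float = 0.05
    ratio_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.ratio_cutoff <= 0:
            raise ValueError("ratio_cutoff must be positive")


def _group_masks(
    ecology: pd.DataFrame, grouping: str, potential_policy: str = "include"
) -> tuple[pd.Series, pd.Series]:
    """(focal, reference) boolean masks; 'unknown' genomes are always
    excluded. For the endophyte grouping, 'potential' endophytes join the
    focal group under the default include policy and are dropped entirely
    under exclude."""
    if grouping == "endophyte":
        col = ecology["endophyte"]
        if potential_policy == "include":
            focal = col.isin(["yes", "potential"])
        elif potential_policy == "exclude":
            focal = col == "yes"
        else:
            raise ValueError("potential_policy must be 'include' or 'exclude'")
        reference = col == "no"
    elif grouping == "nutritional_mode":
        col = ecology["nutritional_mode"]
        focal = col == "mycotroph"
        reference = col == "saprotroph"
    else:
        raise ValueError("grouping must be 'endophyte' or 'nutritional_mode'")
    return focal, reference


def group_mean_ratio(
    counts: pd.Series,
    ecology: pd.DataFrame,
    grouping: str,
    potential_policy: str = "include",
) -> float:
    """mean(focal group) / mean(reference group) for one trait.

    Returns +inf when the reference mean is 0 and the focal mean positive;
    NaN (undefined) for 0/0. Raises if either group is empty after label
    filtering.
    """
    counts = counts.reindex(ecology.index)
    focal, reference = _group_masks(ecology, grouping, potential_policy)
    if not focal.any():
        raise ValueError(f"no genomes in the focal group for {grouping!r}")
    if not reference.any():
        raise ValueError(f"no genomes in the reference group for {grouping!r}")
    mean_f = float(counts[focal].mean())
    mean_r = float(counts[reference].mean())
    if mean_r == 0.0:
        if mean_f == 0.0:
            logger.warning("0/0 group means — ratio undefined")
            return float("nan")
        logger.warning("reference group mean is 0 — ratio reported as +inf")
        return float("inf")
    return mean_f / mean_r


def enrichment_ratios(
    traits: pd.DataFrame,
    ecology: pd.DataFrame,
    potential_policy: str = "include",
) -> pd.DataFrame:
    """E:NE and M:S mean-count ratios for every trait column."""
    rows = {
        trait: (
            group_mean_ratio(traits[trait], ecology, "endophyte", potential_policy),
            group_mean_ratio(traits[trait], ecology, "nutritional_mode"),
        )
        for trait in traits.columns
    }
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["ratio_e_ne", "ratio_m_s"]
    )
    out.index.name = "trait_id"
    return out


def _exceeds(ratio: float, cutoff: float) -> bool:
    # +inf exceeds any cutoff; NaN (undefined ratio) never flags
    return bool(ratio > cutoff) if not math.isnan(ratio) else False


def screen_candidates(
    signal: pd.DataFrame,
    ratios: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
    ratio_column: str = "ratio_e_ne",
    d_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag candidate traits from signal statistics and enrichment ratios.

    flag_k is set when K <= signal_cutoff, p_K > alpha, and the chosen ratio
    exceeds ratio_cutoff; flag_lambda analogously from lambda_hat/p_lambda.
    flagged_any = flag_k OR flag_lambda. When ``d_results`` (columns D,
    p_brownian) is given, a parallel flag_d (D > 1 and p_brownian <= alpha
    and ratio > cutoff) is reported without entering flagged_any.
    """
    thresholds = thresholds or ScreenThresholds()
    missing = set(ratios.index) - set(signal.index)
    if missing:
        raise KeyError(f"traits missing from signal results: {sorted(missing)}")
    records = []
    for trait in ratios.index:
        sig = signal.loc[trait]
        ratio = float(ratios.loc[trait, ratio_column])
        enriched = _exceeds(ratio, thresholds.ratio_cutoff)
        flag_k = (
            sig["K"] <= thresholds.signal_cutoff
            and sig["p_K"] > thresholds.alpha
            and enriched
        )
        flag_lambda = (
            sig["lambda_hat"] <= thresholds.signal_cutoff
            and sig["p_lambda"] > thresholds.alpha
            and enriched
        )
        rec = {
            "trait_id": trait,
            "ratio_e_ne": float(ratios.loc[trait].get("ratio_e_ne", np.nan)),
            "ratio_m_s": float(ratios.loc[trait].get("ratio_m_s", np.nan)),
            "K": float(sig["K"]),
            "p_K": float(sig["p_K"]),
            "lambda_hat": float(sig["lambda_hat"]),
            "p_lambda": float(sig["p_lambda"]),
            "flag_k": bool(flag_k),
            "flag_lambda": bool(flag_lambda),
            "flagged_any": bool(flag_k or flag_lambda),
        }
        if d_results is not None and trait in d_results.index:
            drow = d_results.loc[trait]
            rec["D"] = float(drow["D"])
            rec["p_brownian"] = float(drow["p_brownian"])
            rec["flag_d"] = bool(
                drow["D"] > 1.0 and drow["p_brownian"] <= thresholds.alpha and enriched
            )
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("trait_id")


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment: sort raw p ascending, adjusted_i = max over
    j <= i of min(1, (m - j + 1) * p_j), mapped back to the input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adjusted[idx] = running
    return adjusted


def compare_groups_adjusted(
    counts: pd.DataFrame,
    ecology: pd.DataFrame,
    grouping: str = "endophyte",
    method: str = "rank",
    potential_policy: str = "include",
) -> pd.DataFrame:
    """Per-trait two-group comparison with Holm-adjusted p-values.

    ``method='parametric'`` runs Welch's two-sample t-test,
    ``method='rank'`` the Wilcoxon rank-sum (Mann-Whitney) test. Traits
    whose groups have fewer than 2 observations are skipped with a warning.
    Returns statistic, raw p, and Holm-adjusted p per trait.
    """
    focal, reference = _group_masks(ecology, grouping, potential_policy)
    counts = counts.reindex(ecology.index)
    rows = []
    for trait in counts.columns:
        a = counts.loc[focal, trait].dropna().to_numpy(dtype=float)
        b = counts.loc[reference, trait].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("trait %s skipped: group with < 2 observations", trait)
            continue
        if np.ptp(np.concatenate([a, b])) == 0.0:
            stat, p = 0.0, 1.0
        elif method == "parametric":
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        elif method == "rank":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = res.statistic, res.pvalue
        else:
            raise ValueError("method must be 'parametric' or 'rank'")
        rows.append({"trait_id": trait, "statistic": float(stat), "p_raw": float(p)})
    out = pd.DataFrame.from_records(rows)
    if len(out):
        out["p_adjusted"] = holm_adjust(out["p_raw"].to_numpy())
        out = out.set_index("trait_id")
    return out
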