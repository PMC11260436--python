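"""Per-feature group comparisons across severity scores.

For each feature: Kolmogorov-Smirnov normality screening per group, a
classical one-way ANOVA when every group passes (Welch ANOVA otherwise), and
— when the omnibus test is significant — all-pairs Tukey HSD with an
additional Bonferroni correction across the number of features tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import UsageError
from .features import FEATURE_NAMES

ALPHA = 0.05

STAR_BINS = [
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
]


def significance_stars(p: float) -> str:
    """Map a corrected p-value to the conventional star annotation."""
    for bound, stars in STAR_BINS:
        if p <= bound:
            return stars
    return ""


@dataclass
class NormalityResult:
    normal: bool
    testable: bool
    statistic: float = float("nan")
    p_value: float = float("nan")


def normality_screen(
    groups: list[np.ndarray], alpha: float = ALPHA, lilliefors: bool = False
) -> list[NormalityResult]:
    """One-sample KS test of each group's standardized values against N(0,1).

    By default values are standardized with the group's own mean/SD and tested
    against the standard normal (anti-conservative when parameters are
    estimated); ``lilliefors=True`` switches to the Lilliefors-corrected
    variant.  Zero-variance groups are flagged non-testable and non-normal.
    """
    out = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            raise UsageError(f"normality screen needs n >= 3 per group, got {g.size}")
        sd = np.std(g, ddof=1)
        if sd == 0:
            out.append(NormalityResult(normal=False, testable=False))
            continue
        if lilliefors:
            from statsmodels.stats.diagnostic import lilliefors as lf

            stat, p = lf(g, dist="norm")
        else:
            z = (g - np.mean(g)) / sd
            stat, p = stats.kstest(z, "norm")
        out.append(NormalityResult(normal=p >= alpha, testable=True,
                                   statistic=float(stat), p_value=float(p)))
    return out


@dataclass
class OmnibusResult:
    F: float
    p_value: float
    test_used: str  # "anova" | "welch"


def omnibus_test(
    groups: list[np.ndarray],
    force: str | None = None,
    alpha: float = ALPHA,
    lilliefors: bool = False,
) -> OmnibusResult:
    """Classical one-way ANOVA, or Welch ANOVA if any group fails normality."""
    if len(groups) < 2:
        raise UsageError(f"omnibus test needs >= 2 groups, got {len(groups)}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for g in groups:
        if g.size < 2:
            raise UsageError("each group needs n >= 2")
    if force is not None and force not in ("anova", "welch"):
        raise UsageError(f"force must be 'anova' or 'welch', got {force!r}")
    if force is None:
        if any(g.size < 3 for g in groups):
            use_welch = True  # too small to screen; assume non-normal
        else:
            flags = normality_screen(groups, alpha=alpha, lilliefors=lilliefors)
            use_welch = not all(r.normal for r in flags)
    else:
        use_welch = force == "welch"
    if use_welch:
        df = pd.DataFrame({
            "value": np.concatenate(groups),
            "group": np.repeat(np.arange(len(groups)), [len(g) for g in groups]),
        })
        res = pg.welch_anova(data=df, dv="value", between="group")
        p_col = "p_unc" if "p_unc" in res.columns else "p-unc"  # renamed across pingouin versions
        return OmnibusResult(float(res["F"].iloc[0]), float(res[p_col].iloc[0]), "welch")
    F, p = stats.f_oneway(*groups)
    return OmnibusResult(float(F), float(p), "anova")


def posthoc_pairwise(
    groups: list[np.ndarray],
    n_features_for_bonferroni: int = 1,
    labels: list | None = None,
) -> pd.DataFrame:
    """All-pairs Tukey HSD with a Bonferroni factor across tested features.

    Each Tukey p-value (studentized-range distribution) is multiplied by
    ``n_features_for_bonferroni`` and capped at 1.  Pairs with a combined
    n < 3 are skipped with a reason.
    """
    if n_features_for_bonferroni < 1:
        raise UsageError("n_features_for_bonferroni must be >= 1")
    groups = [np.asarray(g, dtype=float) for g in groups]
    labels = labels if labels is not None else list(range(len(groups)))
    valid = [i for i, g in enumerate(groups) if len(g) >= 2]
    res = stats.tukey_hsd(*[groups[i] for i in valid]) if len(valid) >= 2 else None
    pos = {i: j for j, i in enumerate(valid)}
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if len(groups[i]) < 2 or len(groups[j]) < 2 or res is None:
                reason = (
                    "combined n < 3"
                    if len(groups[i]) + len(groups[j]) < 3
                    else "group n < 2"
                )
                rows.append({
                    "group_a": labels[i], "group_b": labels[j],
                    "mean_diff": float("nan"), "p_tukey": float("nan"),
                    "p_corrected": float("nan"), "stars": "",
                    "skipped": reason,
                })
                continue
            p = float(res.pvalue[pos[i], pos[j]])
            p_corr = min(1.0, p * n_features_for_bonferroni)
            rows.append({
                "group_a": labels[i], "group_b": labels[j],
                "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                "p_tukey": p,
                "p_corrected": p_corr,
                "stars": significance_stars(p_corr),
                "skipped": "",
            })
    return pd.DataFrame(rows)


@dataclass
class GroupComparisonReport:
    """Per-feature omnibus results plus pairwise tables for significant features."""

    group_labels: list = field(default_factory=list)
    features: dict = field(default_factory=dict)  # name -> summary dict
    pairwise: dict = field(default_factory=dict)  # name -> pairwise records

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, d in self.features.items():
            row = {"feature": name, "F": d["F"], "p_value": d["p_value"],
                   "test_used": d["test_used"], "significant": d["significant"]}
            for lab, (m, s) in zip(self.group_labels, d["group_mean_sd"]):
                row[f"mean_{lab}"] = m
                row[f"sd_{lab}"] = s
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "group_labels": [int(g) for g in self.group_labels],
            "features": self.features,
            "pairwise": self.pairwise,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def compare_all_features(
    table: pd.DataFrame,
    group_col: str = "score",
    feature_names: list[str] | None = None,
    alpha: float = ALPHA,
    lilliefors: bool = False,
) -> GroupComparisonReport:
    """Run the normality/omnibus/post-hoc battery for every feature.

    The Bonferroni factor in the post-hoc correction is the number of
    features tested; the pairwise table is produced only for features whose
    omnibus p-value is below ``alpha``.
    """
    feature_names = feature_names if feature_names is not None else [
        f for f in FEATURE_NAMES if f in table.columns
    ]
    if not feature_names:
        raise UsageError("no feature columns found in the table")
    labels = sorted(table[group_col].unique())
    if len(labels) < 2:
        raise UsageError(f"need >= 2 groups in column {group_col!r}, got {len(labels)}")
    report = GroupComparisonReport(group_labels=list(labels))
    n_tested = len(feature_names)
    for name in feature_names:
        groups = [table.loc[table[group_col] == lab, name].to_numpy(dtype=float)
                  for lab in labels]
        if any(len(g) < 3 for g in groups):
            norm = [NormalityResult(normal=False, testable=False) for _ in groups]
            res = omnibus_test(groups, force="welch")
        else:
            norm = normality_screen(groups, alpha=alpha, lilliefors=lilliefors)
            res = omnibus_test(
                groups,
                force=None if all(r.testable for r in norm) else "welch",
                alpha=alpha, lilliefors=lilliefors,
            )
        significant = bool(res.p_value < alpha)
        report.features[name] = {
            "group_mean_sd": [
                (float(np.mean(g)), float(np.std(g, ddof=1))) for g in groups
            ],
            "normal_flags": [bool(r.normal) for r in norm],
            "test_used": res.test_used,
            "F": res.F,
            "p_value": res.p_value,
            "significant": significant,
        }
        if significant:
            pw = posthoc_pairwise(groups, n_features_for_bonferroni=n_tested, labels=labels)
            report.pairwise[name] = pw.to_dict(orient="records")
    return report
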