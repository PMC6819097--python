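"""ROI-to-ROI connectivity, neurobehavioral correlation and group statistics.

Resting-state functional connectivity between the four auditory seeds
(left/right Heschl's gyrus, left/right superior temporal gyrus) is the
Pearson correlation of their mean BOLD time courses, Fisher
z-transformed (z = atanh r). Each participant contributes six z values,
one per unordered ROI pair. These, plus the digit-span score, are the
seven predictors correlated (Pearson, two-sided) with each behavioral
or structural measure from the signaling games; significance is
Bonferroni-held at alpha / 7 per behavioral variable (0.05 / 7 = 0.007).
Group-level descriptives use the one-sample Wilcoxon signed-rank test
against zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .game_metrics import MeasureSet, MissingCodeWarning

__all__ = [
    "ROI_LABELS",
    "BEHAVIOR_ROWS",
    "FCProfile",
    "CorrelationTable",
    "fisher_z",
    "inverse_fisher_z",
    "roi_pairwise_fc",
    "correlate_behavior",
    "permutation_calibration",
    "group_descriptives",
    "behavior_frame",
    "render_report",
]

ROI_LABELS: tuple[str, ...] = ("lHG", "rHG", "lSTG", "rSTG")

#: Table-layout rows: report label -> MeasureSet field.
BEHAVIOR_ROWS: tuple[tuple[str, str], ...] = (
    ("Coordination Tone", "coordination_tone"),
    ("Coordination Contour", "coordination_contour"),
    ("Transmission Tone", "transmission_tone"),
    ("Transmission Contour", "transmission_contour"),
    ("Innovation Tone", "innovation_tone"),
    ("Innovation Contour", "innovation_contour"),
    ("Accuracy", "accuracy"),
    ("Proximity", "delta_icr"),
    ("Regularization Tone", "delta_entropy_tone"),
    ("Regularization Contour", "delta_entropy_contour"),
)


def fisher_z(r):
    """Fisher z-transformation z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher z-transformation")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FCProfile:
    """Six labeled ROI-pair Fisher-z values for one participant."""

    participant_id: str
    z: dict[str, float]

    def __post_init__(self) -> None:
        expected = {f"{a}-{b}" for a, b in itertools.combinations(ROI_LABELS, 2)}
        if set(self.z) != expected:
            raise ValueError(f"FC profile must label exactly the pairs {sorted(expected)}")


def roi_pairwise_fc(timeseries: pd.DataFrame, participant_id: str = "") -> FCProfile:
    """Pairwise Pearson correlations of the four ROI time courses, Fisher-z'd.

    ``timeseries`` must have the four ROI labels as columns, at least 30
    samples and no missing values. A zero-variance ROI yields NaN for its
    pairs (flagged with a warning); a duplicated series across two ROIs
    (r = 1, z infinite) is an error.
    """
    missing = [c for c in ROI_LABELS if c not in timeseries.columns]
    if missing:
        raise ValueError(f"time-series table lacks ROI columns {missing}")
    ts = timeseries[list(ROI_LABELS)].to_numpy(dtype=float)
    if ts.shape[0] < 30:
        raise ValueError(f"need at least 30 samples for correlation, got {ts.shape[0]}")
    if np.isnan(ts).any():
        raise ValueError("time series contain missing values")
    z: dict[str, float] = {}
    for a, b in itertools.combinations(range(len(ROI_LABELS)), 2):
        label = f"{ROI_LABELS[a]}-{ROI_LABELS[b]}"
        xa, xb = ts[:, a], ts[:, b]
        if xa.std() == 0 or xb.std() == 0:
            warnings.warn(f"zero-variance ROI in pair {label}; z flagged missing",
                          MissingCodeWarning)
            z[label] = float("nan")
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        if abs(r) >= 1 - 1e-12:
            raise ValueError(f"pair {label}: |r| = 1 (duplicated series?); z undefined")
        z[label] = fisher_z(r)
    return FCProfile(participant_id=participant_id, z=z)


@dataclass
class CorrelationTable:
    """Pearson r / p / n / significance per behavior x predictor cell."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    significant: pd.DataFrame
    family_alpha: float
    n_tests: int

    @property
    def corrected_alpha(self) -> float:
        return self.family_alpha / self.n_tests

    @property
    def corrected_alpha_printed(self) -> float:
        """Corrected threshold at 3-decimal report precision (0.007)."""
        return round(self.corrected_alpha, 3)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.r.index:
            for pred in self.r.columns:
                rows.append({"behavior": b, "predictor": pred,
                             "r": self.r.loc[b, pred], "p": self.p.loc[b, pred],
                             "n": self.n.loc[b, pred],
                             "significant": bool(self.significant.loc[b, pred])})
        return pd.DataFrame(rows)


def behavior_frame(measures: list[MeasureSet] | pd.DataFrame) -> pd.DataFrame:
    """Participant x behavior table with the canonical report labels."""
    if isinstance(measures, pd.DataFrame):
        df = measures
    else:
        df = pd.DataFrame([m.as_dict() for m in measures]).set_index("participant_id")
    return pd.DataFrame({label: df[field] for label, field in BEHAVIOR_ROWS})


def correlate_behavior(predictors: pd.DataFrame, behaviors: pd.DataFrame,
                       family_alpha: float = 0.05, n_tests: int = 7) -> CorrelationTable:
    """Pearson correlation of every behavior with every predictor.

    Rows of both frames are participants (aligned on index). Cells use
    pairwise-complete deletion, with the effective n reported; constant
    columns yield flagged-missing (NaN) cells. Significance is held at
    ``family_alpha / n_tests`` (two-sided p).
    """
    predictors, behaviors = predictors.align(behaviors, join="inner", axis=0)
    if len(predictors) < 3:
        raise ValueError("need at least 3 complete participant rows")
    threshold = family_alpha / n_tests
    r = pd.DataFrame(index=behaviors.columns, columns=predictors.columns, dtype=float)
    p = pd.DataFrame(index=behaviors.columns, columns=predictors.columns, dtype=float)
    n = pd.DataFrame(index=behaviors.columns, columns=predictors.columns, dtype=int)
    for b in behaviors.columns:
        for q in predictors.columns:
            pair = pd.concat([behaviors[b], predictors[q]], axis=1).dropna()
            n.loc[b, q] = len(pair)
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if len(pair) < 3 or x.std() == 0 or y.std() == 0:
                warnings.warn(f"constant or short column in cell ({b}, {q}); flagged",
                              MissingCodeWarning)
                r.loc[b, q] = p.loc[b, q] = float("nan")
                continue
            res = stats.pearsonr(x, y)
            r.loc[b, q] = res.statistic
            p.loc[b, q] = res.pvalue
    significant = p < threshold
    return CorrelationTable(r=r, p=p, n=n, significant=significant,
                            family_alpha=family_alpha, n_tests=n_tests)


def _pearson_p_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided p between columns of X and Y."""
    n = X.shape[0]
    Xc = (X - X.mean(0)) / X.std(0, ddof=1)
    Yc = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    R = Xc.T @ Yc / (n - 1)
    R = np.clip(R, -0.9999999999, 0.9999999999)
    t = R * np.sqrt((n - 2) / (1 - R * R))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return R, p


def permutation_calibration(predictors: pd.DataFrame, behaviors: pd.DataFrame,
                            n_permutations: int = 1000,
                            rng: np.random.Generator | int | None = None,
                            family_alpha: float = 0.05, n_tests: int = 7) -> float:
    """Null false-positive rate of the corrected threshold.

    Shuffles participant labels of the behavior table ``n_permutations``
    times and returns the pooled fraction of behavior x predictor cells
    significant at ``family_alpha / n_tests``. Under the null this rate
    should match the corrected threshold up to binomial error.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    predictors, behaviors = predictors.align(behaviors, join="inner", axis=0)
    X = predictors.to_numpy(dtype=float)
    Y = behaviors.to_numpy(dtype=float)
    threshold = family_alpha / n_tests
    hits = 0
    cells = X.shape[1] * Y.shape[1]
    for _ in range(n_permutations):
        perm = rng.permutation(Y.shape[0])
        _, p = _pearson_p_matrix(X, Y[perm])
        hits += int((p < threshold).sum())
    return hits / (n_permutations * cells)


def group_descriptives(behaviors: pd.DataFrame) -> pd.DataFrame:
    """Median, mean and one-sample Wilcoxon signed-rank test against zero.

    Zero differences are dropped, tied ranks averaged, and the normal
    approximation used (two-sided p). A measure with all-zero values has
    an undefined test and is flagged with NaN statistics.
    """
    if len(behaviors) < 5:
        raise ValueError("need at least 5 participants for group descriptives")
    rows = []
    for col in behaviors.columns:
        x = behaviors[col].dropna().to_numpy(dtype=float)
        row = {"measure": col, "n": len(x), "median": float(np.median(x)),
               "mean": float(np.mean(x))}
        if np.all(x == 0):
            row.update({"wilcoxon_w": float("nan"), "z": float("nan"), "p": float("nan")})
        else:
            res = stats.wilcoxon(x, zero_method="wilcox", correction=False,
                                 method="approx", alternative="two-sided")
            row.update({"wilcoxon_w": float(res.statistic),
                        "z": float(res.zstatistic), "p": float(res.pvalue)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")


def render_report(table: CorrelationTable, descriptives: pd.DataFrame | None,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write the correlation table and descriptives as CSV plus a
    human-readable text table with ** around Bonferroni-significant r."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"correlations": out_dir / "correlations.csv",
             "report": out_dir / "report.txt"}
    table.to_long_frame().to_csv(paths["correlations"], index=False)

    width = max(len(str(b)) for b in table.r.index) + 2
    lines = [
        f"Pearson correlations; Bonferroni threshold alpha = "
        f"{table.family_alpha}/{table.n_tests} = {table.corrected_alpha_printed:.3f}",
        "",
        " " * width + "  ".join(f"{c:>10}" for c in table.r.columns),
    ]
    for b in table.r.index:
        cells = []
        for q in table.r.columns:
            val = table.r.loc[b, q]
            text = "   nan" if pd.isna(val) else f"{val:6.3f}"
            if bool(table.significant.loc[b, q]):
                text = f"**{text.strip()}**"
            cells.append(f"{text:>10}")
        lines.append(f"{b:<{width}}" + "  ".join(cells))
    if descriptives is not None:
        paths["descriptives"] = out_dir / "descriptives.csv"
        descriptives.to_csv(paths["descriptives"])
        lines += ["", "Group descriptives (one-sample Wilcoxon signed-rank vs 0):",
                  descriptives.to_string()]
    paths["report"].write_text("\n".join(lines) + "\n")
    return paths
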