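"""Parameter sweep, cleft-depth classification and SVM feature importance.

The sweep varies four cellular parameters of the single-cleft model --
mitosis rate (MR), cleft contractility (FPP lambda), cleft cell-cell
contact energy (CC) and cleft cell-matrix contact energy (CM) -- and
classifies each run's final depth into four classes bounded at the
ex-vivo quartile depths 17.8 / 30.5 / 40.7 um.  Parameter importance is
ranked by the drop in cross-validated RBF-SVM accuracy when a feature is
removed: the bigger the drop, the more the parameter matters for cleft
progression.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_validate
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CLASS_LABELS = ("failed", "non_progressive", "progressive",
                "super_progressive")
CLASS_BOUNDS_UM = (17.8, 30.5, 40.7)
FEATURES = ("MR", "FPP", "CC", "CM")


def classify_depth(depth_um: float,
                   bounds: tuple[float, float, float] = CLASS_BOUNDS_UM) -> str:
    """Depth class: [lo, hi) intervals, upper class closed at the top bound."""
    if not np.isfinite(depth_um) or depth_um < 0:
        raise ValueError(f"depth must be finite and >= 0, got {depth_um}")
    lo, mid, hi = bounds
    if depth_um < lo:
        return "failed"
    if depth_um < mid:
        return "non_progressive"
    if depth_um <= hi:
        return "progressive"
    return "super_progressive"


def assign_combo_class(depths_um) -> str:
    """Overall class of one parameter combination across its replicates:
    majority class; ties resolved by classifying the median depth."""
    depths = np.asarray(list(depths_um), dtype=float)
    if len(depths) == 0:
        raise ValueError("need at least one replicate outcome")
    labels = [classify_depth(d) for d in depths]
    counts = pd.Series(labels).value_counts()
    top = counts[counts == counts.max()]
    if len(top) == 1:
        return str(top.index[0])
    return classify_depth(float(np.median(depths)))


@dataclass
class SweepGrid:
    """Parameter levels of the full factorial sweep (4 * 6 * 5 * 5 = 600)."""

    mr_values: tuple = (0.5, 1.0, 2.0, 3.0)
    fpp_values: tuple = (1.0, 5.0, 10.0, 15.0, 20.0, 30.0)
    cc_values: tuple = (1.0, 5.0, 10.0, 15.0, 20.0)
    cm_values: tuple = (1.0, 2.0, 3.0, 4.0, 5.0)
    replicates: int = 40

    def combos(self) -> list[tuple]:
        return list(itertools.product(self.mr_values, self.fpp_values,
                                      self.cc_values, self.cm_values))

    def __len__(self) -> int:
        return len(self.combos())


def combo_seed(master_seed: int, combo_index: int, replicate: int) -> int:
    """Derived seed, a pure function of (master seed, combo, replicate)."""
    ss = np.random.SeedSequence([int(master_seed), int(combo_index),
                                 int(replicate)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_sweep(grid: SweepGrid, mcs: int = 1500, seed: int = 0,
              config=None, executor=None, progress: bool = False
              ) -> pd.DataFrame:
    """Run the factorial sweep; one row per (combination, replicate).

    Each run builds the single-cleft model with the combination's
    overrides, simulates ``mcs`` steps and measures the final depth.
    Failures are recorded as NaN depth rather than aborting the table.
    Seed-deterministic per (combination, replicate).
    """
    from .simulate import run_condition  # deferred: avoids an import cycle
    jobs = []
    for i, (mr, fpp, cc, cm) in enumerate(grid.combos()):
        for rep in range(grid.replicates):
            jobs.append((i, mr, fpp, cc, cm, rep,
                         combo_seed(seed, i, rep)))

    def one(job):
        i, mr, fpp, cc, cm, rep, s = job
        try:
            res = run_condition("base", seed=s, mcs=mcs, config=config,
                                overrides={"mitosis_rate": mr,
                                           "fpp_lambda_cleft": fpp,
                                           "cc_cleft": cc, "cm_cleft": cm})
            depth = res["depth_um"]
        except Exception:
            depth = float("nan")
        return {"combo": i, "MR": mr, "FPP": fpp, "CC": cc, "CM": cm,
                "rep": rep, "seed": s, "depth_um": depth,
                "label": (classify_depth(depth)
                          if np.isfinite(depth) else "error")}

    mapper = executor if executor is not None else map
    it = mapper(one, jobs)
    if progress:
        from tqdm import tqdm
        it = tqdm(it, total=len(jobs))
    return pd.DataFrame(list(it))


def combo_classes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Collapse the outcome table to one class per parameter combination."""
    rows = []
    for (mr, fpp, cc, cm), sub in outcomes.groupby(["MR", "FPP", "CC", "CM"]):
        depths = sub["depth_um"].dropna()
        label = assign_combo_class(depths) if len(depths) else "error"
        rows.append({"MR": mr, "FPP": fpp, "CC": cc, "CM": cm,
                     "n": len(depths),
                     "median_depth_um": (float(depths.median())
                                         if len(depths) else float("nan")),
                     "label": label})
    return pd.DataFrame(rows)


def feature_subsets() -> list[tuple[str, ...]]:
    """The 15 non-empty subsets of {MR, FPP, CC, CM}."""
    out = []
    for r in range(1, 5):
        out += list(itertools.combinations(FEATURES, r))
    return out


def feature_importance(combos: pd.DataFrame, rng=None, n_per_class: int = 50,
                       C: float = 1.0, gamma: str | float = "scale",
                       n_folds: int = 10) -> pd.DataFrame:
    """Accuracy of an RBF SVM per feature subset, 10-fold cross-validated.

    Draws ``n_per_class`` combinations per class (without replacement
    where possible, else with replacement and flagged), standardizes the
    features, and reports mean +/- sd training and testing accuracy plus
    the testing-accuracy drop versus the full feature set.
    """
    rng = np.random.default_rng(rng)
    present = [c for c in CLASS_LABELS if (combos["label"] == c).any()]
    if len(present) < 2:
        raise ValueError("need at least two classes for feature importance")
    parts = []
    resampled = False
    for cls in present:
        sub = combos[combos["label"] == cls]
        replace = len(sub) < n_per_class
        resampled |= replace
        idx = rng.choice(sub.index.to_numpy(), size=n_per_class,
                         replace=replace)
        parts.append(combos.loc[idx])
    sample = pd.concat(parts, ignore_index=True)
    y = sample["label"].to_numpy()
    n_folds = min(n_folds, n_per_class)  # stratified folds need members
    rows = []
    full_key = tuple(FEATURES)
    accs = {}
    for subset in feature_subsets():
        X = sample[list(subset)].to_numpy(dtype=float)
        clf = make_pipeline(StandardScaler(),
                            SVC(kernel="rbf", C=C, gamma=gamma))
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                             random_state=int(rng.integers(2 ** 31)))
        res = cross_validate(clf, X, y, cv=cv, return_train_score=True)
        accs[subset] = res
        rows.append({
            "subset": "+".join(subset),
            "n_features": len(subset),
            "train_acc": float(res["train_score"].mean()),
            "train_sd": float(res["train_score"].std()),
            "test_acc": float(res["test_score"].mean()),
            "test_sd": float(res["test_score"].std()),
            "resampled": resampled,
        })
    df = pd.DataFrame(rows)
    full_acc = float(
        df.loc[df["subset"] == "+".join(full_key), "test_acc"].iloc[0])
    df["drop_vs_full"] = full_acc - df["test_acc"]
    return df


def removal_importance(importance: pd.DataFrame) -> pd.Series:
    """Accuracy drop when each single feature is removed (3-feature rows)."""
    out = {}
    for f in FEATURES:
        others = [g for g in FEATURES if g != f]
        key = "+".join(others)
        row = importance[importance["subset"] == key]
        out[f] = float(row["drop_vs_full"].iloc[0])
    return pd.Series(out).sort_values(ascending=False)


def progressive_value_distribution(combos: pd.DataFrame,
                                   label: str = "progressive") -> dict:
    """Per-parameter value histograms restricted to one outcome class."""
    sub = combos[combos["label"] == label]
    if len(sub) == 0:
        raise ValueError(f"no combinations in class {label!r}")
    out = {}
    for f in FEATURES:
        counts = sub[f].value_counts().sort_index()
        out[f] = {"counts": counts,
                  "peak": float(counts.idxmax()),
                  "variance": float(sub[f].var(ddof=0))}
    return out
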