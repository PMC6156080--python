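"""Population-level measures: binned rasters, pairwise Pearson synchrony,
surrogate (shuffled) nulls, distance-correlation fits, spatial-clustering
permutation tests and group comparisons.

Transient onsets are binned into 328-ms occupancy rasters; synchrony of a
cell pair is the Pearson correlation of their binary bin vectors.  Chance
synchrony is estimated by a two-step surrogate: raster identities are
reassigned to randomly selected ROIs, then event times are redistributed
uniformly subject to a 1-s minimum separation.  Astrocyte-like cells and
silent cells carry no information for these measures and are excluded
before correlation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .synthetic import shuffle_times_exact

log = logging.getLogger("mcca.network")

DEFAULT_BIN_WIDTH_S = 0.328
DEFAULT_SHUFFLE_MIN_SEP_S = 1.0

#: single-letter codes used to name pair classes (SS, SL, ..., HH)
CLASS_CODES = {"silent": "S", "low": "L", "medium": "M", "hyper": "H"}
CODE_ORDER = "SLMH"

PAIR_COLUMNS = ["cell_i", "cell_j", "pearson_r", "distance_um", "pair_class"]


class NetworkError(ValueError):
    """Raised for invalid network-metric inputs."""


@dataclass
class RasterMatrix:
    """Binary event-occupancy raster, (n_bins x n_cells)."""

    occupancy: np.ndarray
    bin_width_s: float = DEFAULT_BIN_WIDTH_S
    t0: float = 0.0
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 2:
            raise NetworkError("occupancy must be (n_bins, n_cells)")
        if self.bin_width_s <= 0:
            raise NetworkError("bin width must be positive")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i:04d}" for i in range(self.n_cells)]
        if len(self.cell_ids) != self.n_cells:
            raise NetworkError("cell_ids length mismatch")

    @property
    def n_bins(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_cells(self) -> int:
        return self.occupancy.shape[1]


def bin_raster(
    event_times: Sequence[np.ndarray] | Mapping[str, np.ndarray],
    duration_s: float,
    bin_width_s: float = DEFAULT_BIN_WIDTH_S,
    cell_ids: list[str] | None = None,
) -> RasterMatrix:
    """Bin per-cell event times into a binary occupancy raster.

    Bins are half-open ``[b*w, (b+1)*w)``; the trailing partial bin is
    dropped.  An event time at or beyond ``duration_s`` is an error.
    """
    if bin_width_s <= 0:
        raise NetworkError("bin width must be positive")
    if isinstance(event_times, Mapping):
        cell_ids = cell_ids or [str(k) for k in event_times.keys()]
        trains = list(event_times.values())
    else:
        trains = list(event_times)
    # tolerate float representation at exact multiples (32.8 / 0.328 == 100)
    n_bins = int(np.floor(duration_s / bin_width_s * (1 + 1e-12)))
    occ = np.zeros((n_bins, len(trains)), dtype=bool)
    for c, times in enumerate(trains):
        times = np.asarray(times, dtype=float)
        if times.size and times.max() >= duration_s:
            raise NetworkError(
                f"cell {c}: event time {times.max():.3f}s >= duration {duration_s}s"
            )
        b = np.floor(times / bin_width_s).astype(int)
        b = b[b < n_bins]  # trailing partial bin dropped
        occ[b, c] = True
    return RasterMatrix(occ, bin_width_s=bin_width_s, cell_ids=cell_ids or [])


def pearson_matrix(
    raster: RasterMatrix, active_only: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r of the binary bin vectors.

    Returns ``(r, kept)`` where ``r`` is the correlation matrix over the
    ``kept`` cell indices.  Zero-variance cells (silent by construction)
    are excluded with a log entry when ``active_only``.
    """
    x = raster.occupancy.astype(float)
    var = x.var(axis=0)
    if active_only:
        kept = np.flatnonzero(var > 0)
        dropped = raster.n_cells - kept.size
        if dropped:
            log.info("pearson_matrix: excluded %d zero-variance cell(s)", dropped)
    else:
        kept = np.arange(raster.n_cells)
        if np.any(var[kept] == 0):
            raise NetworkError("zero-variance cell in correlation with active_only=False")
    if kept.size < 2:
        raise NetworkError("need at least 2 active cells for pairwise correlation")
    r = np.corrcoef(x[:, kept], rowvar=False)
    return r, kept


def pairwise_distances(roi_xy_um: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix in micrometres (symmetric, zero diagonal)."""
    xy = np.asarray(roi_xy_um, dtype=float)
    if not np.all(np.isfinite(xy)):
        raise NetworkError("coordinates must be finite")
    return squareform(pdist(xy))


def pair_class(class_a: str, class_b: str) -> str:
    """Order-normalised two-letter pair code (e.g. low+medium -> 'LM')."""
    a, b = CLASS_CODES[class_a], CLASS_CODES[class_b]
    return "".join(sorted((a, b), key=CODE_ORDER.index))


def pair_table(
    raster: RasterMatrix,
    activity_classes: Sequence[str],
    roi_xy_um: np.ndarray,
    active_only: bool = True,
) -> pd.DataFrame:
    """Per-pair statistics: Pearson r, distance and pair class.

    One row per unordered pair of included (active) cells, columns
    ``cell_i, cell_j, pearson_r, distance_um, pair_class``.
    """
    if len(activity_classes) != raster.n_cells or len(roi_xy_um) != raster.n_cells:
        raise NetworkError("classes/coordinates must match the raster cells")
    r, kept = pearson_matrix(raster, active_only=active_only)
    D = pairwise_distances(roi_xy_um)
    rows = []
    for a in range(kept.size):
        for b in range(a + 1, kept.size):
            i, j = int(kept[a]), int(kept[b])
            rows.append(
                (
                    raster.cell_ids[i],
                    raster.cell_ids[j],
                    float(r[a, b]),
                    float(D[i, j]),
                    pair_class(activity_classes[i], activity_classes[j]),
                )
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


# ---------------------------------------------------------------------------
# surrogates
# ---------------------------------------------------------------------------

def shuffle_events(
    event_times: Sequence[np.ndarray],
    duration_s: float,
    mode: str = "full",
    min_sep_s: float = DEFAULT_SHUFFLE_MIN_SEP_S,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Surrogate event trains destroying co-timing but conserving counts.

    Modes: ``permute_identity`` reassigns each cell's train to a randomly
    selected ROI (a bijection on cells); ``shuffle_times`` redistributes
    each train uniformly in time subject to successive gaps >= 1 s;
    ``full`` applies both, in that order.  Per-cell event *counts* after
    ``permute_identity`` follow the permuted assignment; the time shuffle
    conserves each train's count exactly.
    """
    if mode not in ("permute_identity", "shuffle_times", "full"):
        raise NetworkError(f"unknown shuffle mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng()
    trains = [np.asarray(t, dtype=float) for t in event_times]
    if mode in ("permute_identity", "full"):
        perm = rng.permutation(len(trains))
        trains = [trains[p] for p in perm]
    if mode in ("shuffle_times", "full"):
        out = []
        for c, t in enumerate(trains):
            if (t.size - 1) * min_sep_s >= duration_s:
                raise NetworkError(
                    f"cell {c}: {t.size} events cannot keep {min_sep_s}s apart "
                    f"within {duration_s}s"
                )
            out.append(shuffle_times_exact(t.size, duration_s, min_sep_s, rng))
        trains = out
    return trains


def shuffle_raster(
    raster_or_events,
    duration_s: float | None = None,
    mode: str = "full",
    min_sep_s: float = DEFAULT_SHUFFLE_MIN_SEP_S,
    rng: np.random.Generator | None = None,
    bin_width_s: float = DEFAULT_BIN_WIDTH_S,
) -> RasterMatrix:
    """Surrogate raster from event trains (see :func:`shuffle_events`)."""
    if isinstance(raster_or_events, RasterMatrix):
        raster = raster_or_events
        w = raster.bin_width_s
        duration = raster.n_bins * w
        events = [
            np.flatnonzero(raster.occupancy[:, c]) * w + w / 2.0
            for c in range(raster.n_cells)
        ]
        bin_width_s = w
    else:
        if duration_s is None:
            raise NetworkError("duration_s is required for event-train input")
        events = raster_or_events
        duration = duration_s
    shuffled = shuffle_events(events, duration, mode=mode, min_sep_s=min_sep_s, rng=rng)
    return bin_raster(shuffled, duration, bin_width_s=bin_width_s)


# ---------------------------------------------------------------------------
# distance-correlation relationship
# ---------------------------------------------------------------------------

@dataclass
class DistanceFit:
    slope: float            # Pearson r per um
    intercept: float
    p_value: float          # two-sided, slope != 0
    r_value: float
    n_pairs: int


def distance_correlation_fit(pairs: pd.DataFrame) -> DistanceFit:
    """Ordinary least squares of pairwise Pearson r on pairwise distance."""
    if len(pairs) < 3:
        raise NetworkError("need at least 3 pairs for the distance fit")
    d = pairs["distance_um"].to_numpy(dtype=float)
    r = pairs["pearson_r"].to_numpy(dtype=float)
    if np.ptp(d) == 0:
        raise NetworkError("zero distance variance")
    if np.ptp(r) == 0:
        return DistanceFit(0.0, float(r[0]), 1.0, 0.0, len(pairs))
    fit = stats.linregress(d, r)
    return DistanceFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r_value=float(fit.rvalue),
        n_pairs=len(pairs),
    )


def subgroup_pair_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Distribution summary of Pearson r per pair class.

    Classes without any pair are absent from the result (e.g. no
    hyper-involving pairs in a population without hyperactive cells).
    """
    rows = []
    for cls, grp in pairs.groupby("pair_class"):
        r = grp["pearson_r"].to_numpy(dtype=float)
        rows.append(
            (
                cls,
                len(r),
                float(np.mean(r)),
                float(np.median(r)),
                float(np.percentile(r, 25)),
                float(np.percentile(r, 75)),
            )
        )
    out = pd.DataFrame(
        rows, columns=["pair_class", "n_pairs", "mean_r", "median_r", "q25_r", "q75_r"]
    )
    return out.sort_values("pair_class").reset_index(drop=True)


# ---------------------------------------------------------------------------
# spatial clustering permutation test
# ---------------------------------------------------------------------------

def _class_pair_means(D: np.ndarray, labels: np.ndarray, classes: list[str]) -> dict:
    """Mean pairwise distance for every class pair under current labels."""
    out = {}
    idx = {c: np.flatnonzero(labels == c) for c in classes}
    for a, b in itertools.combinations_with_replacement(classes, 2):
        ia, ib = idx[a], idx[b]
        if a == b:
            if ia.size < 2:
                continue
            sub = D[np.ix_(ia, ia)]
            out[pair_class(a, b)] = sub.sum() / (ia.size * (ia.size - 1))
        else:
            if ia.size == 0 or ib.size == 0:
                continue
            out[pair_class(a, b)] = D[np.ix_(ia, ib)].mean()
    return out


def spatial_clustering_test(
    activity_classes: Sequence[str],
    roi_xy_um: np.ndarray,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Permutation test for spatial clustering of functional subgroups.

    The observed mean pairwise distance of every class pair is compared to
    its distribution under random permutations of the labels with cell
    locations fixed.  Two-sided p-values use the add-one estimator
    ``min(1, 2 * min(P[perm <= obs], P[perm >= obs]))``.  Pair classes
    whose member count makes a distance undefined are skipped with a log
    entry; a single-class population yields an empty result.
    """
    labels = np.asarray(list(activity_classes))
    if n_permutations < 100:
        raise NetworkError("need at least 100 permutations")
    classes = sorted(set(labels.tolist()), key=lambda c: CODE_ORDER.index(CLASS_CODES[c]))
    if len(classes) < 2:
        log.info("spatial_clustering_test: single class only, empty result")
        return pd.DataFrame(
            columns=["pair_class", "n_pairs", "observed_mean_um", "p_value"]
        )
    rng = rng if rng is not None else np.random.default_rng()
    D = pairwise_distances(roi_xy_um)
    observed = _class_pair_means(D, labels, classes)
    counts = {c: int(np.sum(labels == c)) for c in classes}
    skipped = [c for c in classes if counts[c] < 2]
    for c in skipped:
        log.info(
            "spatial_clustering_test: class %r has <2 members, within-class "
            "distance skipped", c,
        )

    perm_vals = {k: np.empty(n_permutations) for k in observed}
    for p in range(n_permutations):
        perm_labels = labels[rng.permutation(labels.size)]
        vals = _class_pair_means(D, perm_labels, classes)
        for k in perm_vals:
            perm_vals[k][p] = vals[k]

    rows = []
    for k, obs in observed.items():
        perms = perm_vals[k]
        p_le = (1 + np.sum(perms <= obs)) / (1 + n_permutations)
        p_ge = (1 + np.sum(perms >= obs)) / (1 + n_permutations)
        p_two = min(1.0, 2.0 * min(p_le, p_ge))
        a, b = k[0], k[1]
        code_of = {v: key for key, v in CLASS_CODES.items()}
        na, nb = counts[code_of[a]], counts[code_of[b]]
        n_pairs = na * (na - 1) // 2 if a == b else na * nb
        rows.append((k, n_pairs, float(obs), float(p_two)))
    return (
        pd.DataFrame(rows, columns=["pair_class", "n_pairs", "observed_mean_um", "p_value"])
        .sort_values("pair_class")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# per-recording summary and group comparison
# ---------------------------------------------------------------------------

DEFAULT_FREQ_GRID = tuple(np.arange(0.0, 8.5, 0.5))  # trans/min, 17 points


def population_summary(
    cells: pd.DataFrame,
    field_um: float,
    pairs: pd.DataFrame | None = None,
    freq_grid: Sequence[float] = DEFAULT_FREQ_GRID,
) -> dict:
    """Per-recording summary of the detected population.

    ``cells`` is the per-cell table (see :data:`mcca.io.CELL_COLUMNS`).
    Density counts all stained cells over the imaged area; activity
    statistics are over neurons (astrocyte-like cells excluded), with
    frequency and subgroup proportions over spontaneously active neurons.
    """
    if len(cells) == 0:
        raise NetworkError("summary requires at least one cell")
    neurons = cells[cells["kind"] == "neuron"]
    if len(neurons) == 0:
        raise NetworkError("summary requires at least one neuron")
    active = neurons[neurons["activity_class"] != "silent"]
    area_mm2 = (field_um / 1000.0) ** 2
    freqs = active["frequency_trans_per_min"].to_numpy(dtype=float)
    grid = np.asarray(list(freq_grid), dtype=float)
    cumulative = [float(np.mean(freqs <= g)) if freqs.size else float("nan") for g in grid]
    subgroup = {
        cls: (float(100.0 * np.mean(active["activity_class"] == cls)) if len(active) else 0.0)
        for cls in ("low", "medium", "hyper")
    }
    mean_auc = float(np.nanmean(active["mean_auc"])) if len(active) else float("nan")
    out = {
        "n_cells": int(len(cells)),
        "n_neurons": int(len(neurons)),
        "n_active": int(len(active)),
        "density_cells_per_mm2": float(len(cells) / area_mm2),
        "fraction_active_pct": float(100.0 * len(active) / len(neurons)),
        "mean_frequency_trans_per_min": float(np.mean(freqs)) if freqs.size else float("nan"),
        "mean_auc_dff_s": mean_auc,
        "subgroup_pct_of_active": subgroup,
        "freq_grid_trans_per_min": [float(g) for g in grid],
        "cumulative_freq_fraction": cumulative,
    }
    if pairs is not None and len(pairs):
        out["mean_pairwise_r"] = float(pairs["pearson_r"].mean())
        out["n_pairs"] = int(len(pairs))
    return out


def _normal(values: np.ndarray, alpha: float = 0.05) -> bool:
    """Normality screen (Lilliefors KS); small groups go non-parametric."""
    if values.size < 4 or np.std(values, ddof=1) == 0:
        return False
    from statsmodels.stats.diagnostic import lilliefors

    _, p = lilliefors(values, dist="norm")
    return bool(p > alpha)


def compare_groups(
    summaries_a: Sequence[dict],
    summaries_b: Sequence[dict],
    metrics: Sequence[str] = (
        "fraction_active_pct",
        "mean_frequency_trans_per_min",
        "mean_auc_dff_s",
        "mean_pairwise_r",
    ),
) -> dict:
    """Standard between-group tests on per-recording summaries.

    For each scalar metric: a normality screen on both groups, then an
    unpaired t-test (both normal) or a Mann-Whitney rank-sum test.  The
    subgroup composition is compared with a chi-square test on pooled
    counts, and the cumulative frequency distributions with a two-way
    ANOVA (group x frequency bin).  With fewer than two recordings per
    group the report is marked not testable.
    """
    report: dict = {"n_a": len(summaries_a), "n_b": len(summaries_b), "metrics": {}}
    if len(summaries_a) < 2 or len(summaries_b) < 2:
        report["testable"] = False
        return report
    report["testable"] = True

    for m in metrics:
        a = np.asarray([s[m] for s in summaries_a if m in s], dtype=float)
        b = np.asarray([s[m] for s in summaries_b if m in s], dtype=float)
        if a.size < 2 or b.size < 2:
            report["metrics"][m] = {"testable": False}
            continue
        if _normal(a) and _normal(b):
            stat, p = stats.ttest_ind(a, b)
            test = "t-test"
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
        report["metrics"][m] = {
            "test": test,
            "statistic": float(stat),
            "p_value": float(p),
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "testable": True,
        }

    # subgroup composition: chi-square on pooled active-cell counts
    def counts(summaries):
        tot = {"low": 0.0, "medium": 0.0, "hyper": 0.0}
        for s in summaries:
            n_active = s.get("n_active", 0)
            for cls in tot:
                tot[cls] += s["subgroup_pct_of_active"][cls] * n_active / 100.0
        return [tot[c] for c in ("low", "medium", "hyper")]

    table = np.array([counts(summaries_a), counts(summaries_b)])
    keep = table.sum(axis=0) > 0
    if keep.sum() >= 2 and np.all(table[:, keep].sum(axis=1) > 0):
        chi2, p, dof, _ = stats.chi2_contingency(table[:, keep])
        report["subgroup_chi2"] = {
            "test": "chi-square",
            "statistic": float(chi2),
            "p_value": float(p),
            "dof": int(dof),
            "testable": True,
        }
    else:
        report["subgroup_chi2"] = {"testable": False}

    # cumulative distributions: two-way ANOVA, group x frequency bin
    rows = []
    for g, summaries in (("A", summaries_a), ("B", summaries_b)):
        for k, s in enumerate(summaries):
            for grid_val, frac in zip(
                s["freq_grid_trans_per_min"], s["cumulative_freq_fraction"]
            ):
                rows.append((g, f"{g}{k}", grid_val, frac))
    df = pd.DataFrame(rows, columns=["group", "recording", "freq_bin", "cum_frac"]).dropna()
    if df["group"].nunique() == 2 and df["freq_bin"].nunique() >= 2:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        model = ols("cum_frac ~ C(group) * C(freq_bin)", data=df).fit()
        table2 = sm.stats.anova_lm(model, typ=2)
        report["cumulative_anova"] = {
            "test": "two-way ANOVA",
            "group_p": float(table2.loc["C(group)", "PR(>F)"]),
            "bin_p": float(table2.loc["C(freq_bin)", "PR(>F)"]),
            "interaction_p": float(table2.loc["C(group):C(freq_bin)", "PR(>F)"]),
            "testable": True,
        }
    else:
        report["cumulative_anova"] = {"testable": False}
    return report
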