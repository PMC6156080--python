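"""Synthetic two-photon recordings with known ground truth.

The generator emulates the regimes seen in bulk-loaded (OGB-1-style)
population imaging of cortical layer 2/3: a square ~440-um field holding
~200 somata, a silent subpopulation, active neurons whose transient rates
span the low (<0.3/min), medium (0.3-3/min) and hyperactive (>3/min)
bands, calcium transients with fast rise and seconds-scale decay riding
on a constant baseline with additive Gaussian noise, a minority of
astrocyte-like slow-kinetics cells, and spatially localised co-active
ensembles whose shared events make pairwise correlation decay with
distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import classify_activity
from .io import (
    DEFAULT_FIELD_UM,
    DEFAULT_GRID_PX,
    InputError,
    Recording,
    RoiMaskSet,
)

log = logging.getLogger("mcca.synthetic")


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class KernelParams:
    """Difference-of-exponentials transient kernel, peak-normalised.

    ``k(t) = A * (exp(-t/decay) - exp(-t/rise)) / peak`` for t >= 0, where
    A is the peak dF/F amplitude in percent.
    """

    rise_s: float = 0.1
    decay_s: float = 1.0
    amplitude_dff_pct: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.rise_s < self.decay_s:
            raise ConfigError("kernel requires decay_s > rise_s > 0")
        if self.amplitude_dff_pct <= 0:
            raise ConfigError("kernel amplitude must be positive")

    @property
    def peak_time_s(self) -> float:
        r, d = self.rise_s, self.decay_s
        return r * d / (d - r) * np.log(d / r)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Kernel in dF/F percent at times ``t`` (zero for t < 0)."""
        t = np.asarray(t, dtype=float)
        raw = np.where(
            t >= 0,
            np.exp(-np.maximum(t, 0) / self.decay_s) - np.exp(-np.maximum(t, 0) / self.rise_s),
            0.0,
        )
        tp = self.peak_time_s
        peak = np.exp(-tp / self.decay_s) - np.exp(-tp / self.rise_s)
        return self.amplitude_dff_pct * raw / peak

    def integral_dff_s(self) -> float:
        """Analytic area under the kernel in (dF/F %)*s."""
        tp = self.peak_time_s
        peak = np.exp(-tp / self.decay_s) - np.exp(-tp / self.rise_s)
        return self.amplitude_dff_pct * (self.decay_s - self.rise_s) / peak


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic population.

    Rates are transients/min; the class mixture applies to active neurons
    (silent cells are drawn first with ``silent_fraction``).  Ensembles are
    Gaussian-footprint groups: a cell at distance d from an ensemble centre
    joins with probability ``p_participate * exp(-d^2 / (2 sigma^2))`` and
    then receives that ensemble's shared event times.
    """

    n_cells: int = 200
    field_um: float = DEFAULT_FIELD_UM
    duration_s: float = 360.0
    sampling_rate_hz: float = 15.2
    silent_fraction: float = 0.30
    class_rates_per_min: tuple[float, float, float] = (0.15, 1.0, 4.0)  # low, medium, hyper
    class_weights: tuple[float, float, float] = (0.25, 0.65, 0.10)
    kernel: KernelParams = field(default_factory=KernelParams)
    astrocyte_kernel: KernelParams = field(
        default_factory=lambda: KernelParams(rise_s=0.5, decay_s=8.0, amplitude_dff_pct=40.0)
    )
    astrocyte_fraction: float = 0.0
    astrocyte_rate_per_min: float = 0.5
    noise_sd_dff_pct: float = 8.0
    min_event_sep_s: float = 1.0
    n_ensembles: int = 0
    ensemble_sigma_um: float = 50.0
    ensemble_rate_per_min: float = 1.0
    p_participate: float = 0.5
    baseline_f0: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ConfigError("duration and sampling rate must be positive")
        for name in ("silent_fraction", "astrocyte_fraction", "p_participate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if any(r < 0 for r in self.class_rates_per_min) or self.ensemble_rate_per_min < 0:
            raise ConfigError("rates must be non-negative")
        if any(w < 0 for w in self.class_weights) or sum(self.class_weights) == 0:
            raise ConfigError("class weights must be non-negative and not all zero")
        if self.noise_sd_dff_pct < 0 or self.baseline_f0 <= 0:
            raise ConfigError("noise_sd must be >= 0 and baseline_f0 > 0")
        if self.min_event_sep_s < 0 or self.ensemble_sigma_um <= 0:
            raise ConfigError("min_event_sep_s >= 0 and ensemble_sigma_um > 0 required")


@dataclass
class GroundTruth:
    """Generative truth for one synthetic population."""

    event_times_s: list[np.ndarray]
    rate_per_min: np.ndarray
    activity_class: list[str]
    kind: list[str]
    ensembles: list[list[int]]  # per-cell ensemble memberships

    @property
    def n_cells(self) -> int:
        return len(self.event_times_s)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_cells):
            rows.append(
                (
                    f"cell{i:04d}",
                    self.kind[i],
                    self.activity_class[i],
                    float(self.rate_per_min[i]),
                    len(self.event_times_s[i]),
                    ";".join(str(m) for m in self.ensembles[i]),
                    ";".join(repr(float(t)) for t in self.event_times_s[i]),
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id", "kind", "activity_class", "rate_per_min",
                "n_events", "ensembles", "event_times_s",
            ],
        )

    def write(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def read(cls, path) -> "GroundTruth":
        df = pd.read_csv(Path(path), keep_default_na=False)
        times = [
            np.array([float(x) for x in str(s).split(";") if x != ""])
            for s in df["event_times_s"]
        ]
        ens = [
            [int(x) for x in str(s).split(";") if x != ""] for s in df["ensembles"]
        ]
        return cls(
            event_times_s=times,
            rate_per_min=df["rate_per_min"].to_numpy(dtype=float),
            activity_class=[str(c) for c in df["activity_class"]],
            kind=[str(k) for k in df["kind"]],
            ensembles=ens,
        )


# ---------------------------------------------------------------------------
# event trains
# ---------------------------------------------------------------------------

def _greedy_min_sep(times: np.ndarray, min_sep_s: float) -> np.ndarray:
    """Greedy left-to-right thinning enforcing successive gaps >= min_sep."""
    if times.size == 0 or min_sep_s <= 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_sep_s:
            kept.append(t)
    return np.asarray(kept)


def sample_event_train(
    rate_per_min: float,
    duration_s: float,
    min_sep_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Homogeneous Poisson event train thinned to a minimum separation.

    The candidate process is drawn at intensity ``lambda / (1 - lambda *
    min_sep)`` so that after greedy thinning the retained rate equals the
    nominal rate (the thinned process is a renewal process of rate
    ``lambda' / (1 + lambda' * min_sep)``).  Returns sorted times in s.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    if rate_per_min < 0 or min_sep_s < 0:
        raise ConfigError("rate and min_sep must be non-negative")
    if rate_per_min == 0:
        return np.empty(0)
    lam = rate_per_min / 60.0  # events per second
    occupancy = lam * min_sep_s
    if occupancy >= 1.0:
        raise ConfigError(
            f"rate {rate_per_min}/min with min separation {min_sep_s}s is infeasible"
        )
    if occupancy > 0.5:
        warnings.warn(
            f"rate {rate_per_min}/min is close to the min-separation capacity; "
            "event timing will be strongly regularised",
            stacklevel=2,
        )
    lam_c = lam / (1.0 - occupancy)
    n = rng.poisson(lam_c * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, size=n))
    return _greedy_min_sep(times, min_sep_s)


def shuffle_times_exact(
    n_events: int,
    duration_s: float,
    min_sep_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n_events`` times uniformly on [0, duration) subject to all
    successive gaps >= min_sep, by the order-statistics construction:
    sample uniformly on the compressed interval of length
    ``duration - (n-1) * min_sep`` and re-inflate.
    """
    if n_events == 0:
        return np.empty(0)
    slack = duration_s - (n_events - 1) * min_sep_s
    if slack <= 0:
        raise ConfigError(
            f"{n_events} events cannot be separated by {min_sep_s}s in {duration_s}s"
        )
    u = np.sort(rng.uniform(0.0, slack, size=n_events))
    return u + min_sep_s * np.arange(n_events)


# ---------------------------------------------------------------------------
# trace and movie rendering
# ---------------------------------------------------------------------------

def render_trace(
    event_times_s: np.ndarray,
    kernel: KernelParams,
    duration_s: float,
    sampling_rate_hz: float,
    noise_sd_dff_pct: float,
    f0: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw fluorescence trace from an event train.

    ``trace = f0 * (1 + (sum_k kernel(t - t_k) + noise) / 100)`` with the
    noise i.i.d. Gaussian in dF/F-percent units.
    """
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    dff = np.zeros(n)
    span = kernel.decay_s * 12.0
    for te in np.asarray(event_times_s, dtype=float):
        i0 = max(0, int(np.ceil(te * sampling_rate_hz)))
        i1 = min(n, int(np.ceil((te + span) * sampling_rate_hz)))
        if i0 < i1:
            dff[i0:i1] += kernel.evaluate(t[i0:i1] - te)
    if noise_sd_dff_pct > 0:
        dff = dff + rng.normal(0.0, noise_sd_dff_pct, size=n)
    return f0 * (1.0 + dff / 100.0)


def generate_population(config: GeneratorConfig) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic recording plus its generative ground truth.

    Cell positions are uniform on the field; silent cells, cell kinds and
    activity classes are drawn from the configured fractions; ensemble
    membership is Gaussian-weighted by distance from random ensemble
    centres, and each ensemble's shared event times are injected into the
    trains of all participating cells before min-separation thinning.
    The same seed yields byte-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells

    xy = rng.uniform(0.0, cfg.field_um, size=(n, 2))

    kinds = np.where(rng.uniform(size=n) < cfg.astrocyte_fraction, "astrocyte", "neuron")
    silent = (rng.uniform(size=n) < cfg.silent_fraction) & (kinds == "neuron")
    w = np.asarray(cfg.class_weights, dtype=float)
    w = w / w.sum()
    class_draw = rng.choice(3, size=n, p=w)

    rates = np.zeros(n)
    for i in range(n):
        if kinds[i] == "astrocyte":
            rates[i] = cfg.astrocyte_rate_per_min
        elif silent[i]:
            rates[i] = 0.0
        else:
            rates[i] = cfg.class_rates_per_min[class_draw[i]]

    trains: list[np.ndarray] = []
    for i in range(n):
        trains.append(
            sample_event_train(rates[i], cfg.duration_s, cfg.min_event_sep_s, rng)
            if rates[i] > 0
            else np.empty(0)
        )

    memberships: list[list[int]] = [[] for _ in range(n)]
    if cfg.n_ensembles > 0:
        centers = rng.uniform(0.0, cfg.field_um, size=(cfg.n_ensembles, 2))
        eligible = (kinds == "neuron") & ~silent
        for e in range(cfg.n_ensembles):
            d2 = np.sum((xy - centers[e]) ** 2, axis=1)
            p = cfg.p_participate * np.exp(-d2 / (2.0 * cfg.ensemble_sigma_um**2))
            members = np.flatnonzero(eligible & (rng.uniform(size=n) < p))
            shared = sample_event_train(
                cfg.ensemble_rate_per_min, cfg.duration_s, cfg.min_event_sep_s, rng
            )
            for m in members:
                memberships[m].append(e)
                merged = np.sort(np.concatenate((trains[m], shared)))
                trains[m] = _greedy_min_sep(merged, cfg.min_event_sep_s)

    classes = [
        classify_activity(rates[i], has_events=trains[i].size > 0) for i in range(n)
    ]

    traces = np.empty((int(round(cfg.duration_s * cfg.sampling_rate_hz)), n))
    for i in range(n):
        kern = cfg.astrocyte_kernel if kinds[i] == "astrocyte" else cfg.kernel
        traces[:, i] = render_trace(
            trains[i], kern, cfg.duration_s, cfg.sampling_rate_hz,
            cfg.noise_sd_dff_pct, cfg.baseline_f0, rng,
        )
    np.clip(traces, 0.0, None, out=traces)

    rec = Recording(
        traces=traces,
        sampling_rate_hz=cfg.sampling_rate_hz,
        roi_xy_um=xy,
        field_um=cfg.field_um,
    )
    truth = GroundTruth(
        event_times_s=trains,
        rate_per_min=rates,
        activity_class=classes,
        kind=list(kinds),
        ensembles=memberships,
    )
    return rec, truth



def make_grid_masks(
    n_cells: int,
    grid_px: int = DEFAULT_GRID_PX,
    roi_radius_px: int = 4,
    field_um: float = DEFAULT_FIELD_UM,
    rng: np.random.Generator | None = None,
) -> RoiMaskSet:
    """Disjoint circular ROI masks on a regular grid (for round-trip tests)."""
    per_row = int(np.ceil(np.sqrt(n_cells)))
    pitch = grid_px // per_row
    if pitch < 2 * roi_radius_px + 1:
        raise ConfigError("too many ROIs for the grid at this radius")
    yy, xx = np.mgrid[0:grid_px, 0:grid_px]
    masks = []
    for i in range(n_cells):
        r = i // per_row
        c = i % per_row
        cy = r * pitch + pitch // 2
        cx = c * pitch + pitch // 2
        masks.append((yy - cy) ** 2 + (xx - cx) ** 2 <= roi_radius_px**2)
    return RoiMaskSet(masks=np.stack(masks), pixel_size_um=field_um / grid_px)


def render_movie(
    recording: Recording,
    masks: RoiMaskSet,
    rng: np.random.Generator | None = None,
    pixel_noise_sd: float = 0.0,
    background: float | None = None,
) -> np.ndarray:
    """Image stack in which each ROI's pixels follow the cell's trace.

    Background pixels are constant; optional per-pixel Gaussian noise is
    added on top.  Masks must not overlap.  Without noise,
    :func:`mcca.io.extract_roi_traces` recovers the traces exactly.
    """
    if masks.n_cells != recording.n_cells:
        raise InputError("mask count does not match the recording")
    union = masks.masks.sum(axis=0)
    if np.any(union > 1):
        raise InputError("ROI masks overlap")
    h, w = masks.grid_shape
    n_frames = recording.n_frames
    if background is None:
        background = float(np.median(recording.traces[0]))
    stack = np.full((n_frames, h, w), background)
    for i, m in enumerate(masks.masks):
        stack[:, m] = recording.traces[:, i][:, None]
    if pixel_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        stack = stack + rng.normal(0.0, pixel_noise_sd, size=stack.shape)
    return stack
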