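"""Single-molecule FRET burst analysis of binned two-channel traces.

A dual-labelled oligomer diffusing through the confocal volume produces a
coincident burst in the donor and acceptor channels; monomers appear in
the donor channel only.  From each coincident burst the pipeline derives

* FRET efficiency       E = I_A / (I_A + gamma * I_D)
* apparent size (mers)  2 * (I_D + I_A / gamma) / I_monomer

with I_A, I_D the background-corrected channel intensities, gamma the
instrument detection-correction factor (default 0.99) and I_monomer the
mean donor intensity of monomeric (non-coincident, single-bin) bursts.
The factor of two reflects the 1:1 donor:acceptor labelling stoichiometry.

Bursts with apparent size above 150 monomer units or spanning multiple
consecutive bins are discarded as fibrils or dust.  Retained efficiencies
are histogrammed with bin width 0.05 and the histogram is fitted with a
baseline-plus-Gaussian ("GaussAmp") model

    y = y0 + A * exp(-(x - x_c)^2 / (2 w^2))

whose centre x_c is the reported mean FRET efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "InstrumentParams",
    "Burst",
    "MonomerBrightness",
    "FretHistogram",
    "GaussAmpFit",
    "OligomerSummary",
    "detect_bursts",
    "fret_efficiency",
    "estimate_monomer_brightness",
    "apparent_size",
    "filter_oligomer_bursts",
    "fret_histogram",
    "gaussamp_fit",
    "oligomer_fraction",
    "analyze_trace",
]

DEFAULT_GAMMA = 0.99
SIZE_CUTOFF = 150.0
HIST_BIN_WIDTH = 0.05


@dataclass(frozen=True)
class InstrumentParams:
    """Instrument calibration: gamma factor, per-channel background, threshold."""

    gamma: float = DEFAULT_GAMMA
    donor_background: float = 0.0
    acceptor_background: float = 0.0
    burst_threshold_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.donor_background < 0 or self.acceptor_background < 0:
            raise ValueError("backgrounds must be >= 0")

    def threshold(self, background: float) -> float:
        """Detection threshold in raw counts: bg + k * sqrt(bg)."""
        return background + self.burst_threshold_sd * np.sqrt(background)


@dataclass
class Burst:
    """One detected fluorescence event (a maximal run of burst bins).

    ``I_D`` / ``I_A`` are background-subtracted intensities summed over
    the run, clipped at zero; ``coincident`` is True when both channels
    individually exceeded their detection threshold somewhere in the run.
    """

    bin: int
    I_D: float
    I_A: float
    coincident: bool
    run_length: int

    def __post_init__(self) -> None:
        if self.I_D < 0 or self.I_A < 0:
            raise ValueError("corrected intensities must be >= 0")


@dataclass(frozen=True)
class MonomerBrightness:
    I_monomer: float

    def __post_init__(self) -> None:
        if self.I_monomer <= 0:
            raise ValueError("I_monomer must be > 0")


@dataclass(frozen=True)
class FretHistogram:
    """Efficiency histogram: 20 bins of width 0.05 spanning [0, 1]."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


@dataclass(frozen=True)
class GaussAmpFit:
    y0: float
    A: float
    x_c: float
    w: float
    converged: bool


@dataclass(frozen=True)
class OligomerSummary:
    n_oligomer_bursts: int
    n_monomer_bursts: int
    mass_fraction: float  # percent of monomer-equivalents in oligomers
    mean_apparent_size: float


def detect_bursts(trace: pd.DataFrame, params: InstrumentParams) -> list[Burst]:
    """Find maximal runs of above-threshold bins and summarise each as a Burst.

    A bin is a burst bin when either channel exceeds its background mean
    plus ``burst_threshold_sd`` standard deviations (Poisson: sqrt of the
    mean).  Corrected intensities are counts minus background, clipped at
    zero, summed over the run.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    d = trace["donor_counts"].to_numpy(dtype=float)
    a = trace["acceptor_counts"].to_numpy(dtype=float)
    bins = trace["bin_index"].to_numpy()
    d_thr = params.threshold(params.donor_background)
    a_thr = params.threshold(params.acceptor_background)
    d_hit = d > d_thr
    a_hit = a > a_thr
    hit = d_hit | a_hit

    bursts: list[Burst] = []
    i = 0
    n = len(trace)
    while i < n:
        if not hit[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hit[j + 1] and bins[j + 1] == bins[j] + 1:
            j += 1
        sl = slice(i, j + 1)
        I_D = float(np.clip(d[sl] - params.donor_background, 0, None).sum())
        I_A = float(np.clip(a[sl] - params.acceptor_background, 0, None).sum())
        bursts.append(
            Burst(
                bin=int(bins[i]),
                I_D=I_D,
                I_A=I_A,
                coincident=bool(d_hit[sl].any() and a_hit[sl].any()),
                run_length=j - i + 1,
            )
        )
        i = j + 1
    return bursts


def fret_efficiency(burst: Burst, gamma: float = DEFAULT_GAMMA) -> float:
    """FRET efficiency E = I_A / (I_A + gamma * I_D)."""
    denom = burst.I_A + gamma * burst.I_D
    if denom <= 0:
        raise ValueError("zero total intensity: efficiency undefined")
    return burst.I_A / denom


def estimate_monomer_brightness(bursts: list[Burst]) -> MonomerBrightness:
    """Mean donor intensity of monomeric bursts.

    Monomeric bursts are those that are non-coincident (donor channel
    only) and occupy a single bin.
    """
    vals = [b.I_D for b in bursts if not b.coincident and b.run_length == 1]
    if not vals:
        raise ValueError("no non-coincident single-bin bursts to estimate from")
    return MonomerBrightness(I_monomer=float(np.mean(vals)))


def apparent_size(
    burst: Burst, gamma: float, mono: MonomerBrightness
) -> float:
    """Apparent oligomer size, 2 * (I_D + I_A / gamma) / I_monomer."""
    return 2.0 * (burst.I_D + burst.I_A / gamma) / mono.I_monomer


def filter_oligomer_bursts(
    bursts: list[Burst],
    gamma: float,
    mono: MonomerBrightness,
) -> tuple[list[Burst], pd.DataFrame]:
    """Select analysable oligomeric bursts.

    Retains coincident, single-bin bursts with apparent size <= 150
    monomer units.  Species larger than 150-mers are taken to be fibrillar
    and multi-bin events to be dust; both are removed.  Returns the
    retained bursts and a per-burst log with the removal reason
    (``retained``, ``not_coincident``, ``multi_bin``, ``too_large``).
    """
    retained: list[Burst] = []
    rows = []
    for b in bursts:
        size = apparent_size(b, gamma, mono)
        if not b.coincident:
            reason = "not_coincident"
        elif b.run_length >= 2:
            reason = "multi_bin"
        elif size > SIZE_CUTOFF:
            reason = "too_large"
        else:
            reason = "retained"
            retained.append(b)
        rows.append(
            {
                "bin": b.bin,
                "I_D": b.I_D,
                "I_A": b.I_A,
                "run_length": b.run_length,
                "coincident": b.coincident,
                "apparent_size": size,
                "reason": reason,
            }
        )
    return retained, pd.DataFrame(rows)


def fret_histogram(values: np.ndarray) -> FretHistogram:
    """Histogram efficiencies into 20 bins of width 0.05 on [0, 1].

    Bins are left-closed right-open except the final bin, which is closed
    so E = 1 is representable.
    """
    values = np.asarray(values, dtype=float)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("FRET efficiencies must lie in [0, 1]")
    edges = np.round(np.arange(0.0, 1.0 + HIST_BIN_WIDTH / 2, HIST_BIN_WIDTH), 10)
    counts, _ = np.histogram(values, bins=edges)  # numpy closes the last bin
    return FretHistogram(edges=edges, counts=counts)


def _gaussamp(x, y0, A, x_c, w):
    return y0 + A * np.exp(-((x - x_c) ** 2) / (2.0 * w**2))


def gaussamp_fit(hist: FretHistogram) -> GaussAmpFit:
    """Nonlinear least-squares fit of the baseline-plus-Gaussian model.

    Initialised at (min count, max - min, argmax centre, 0.1) with bounds
    x_c in [0, 1], w in (0, 1], A >= 0.  Non-convergence is reported via
    ``converged=False`` rather than raised.
    """
    x = hist.centers
    y = hist.counts.astype(float)
    if np.count_nonzero(y) < 4:
        raise ValueError("need >= 4 non-zero histogram bins to fit")
    p0 = [float(y.min()), float(y.max() - y.min()), float(x[np.argmax(y)]), 0.1]
    p0[1] = max(p0[1], 1e-9)
    bounds = ([-np.inf, 0.0, 0.0, 1e-9], [np.inf, np.inf, 1.0, 1.0])
    try:
        popt, _ = curve_fit(_gaussamp, x, y, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except RuntimeError:
        popt = p0
        converged = False
    return GaussAmpFit(
        y0=float(popt[0]),
        A=float(popt[1]),
        x_c=float(popt[2]),
        w=float(popt[3]),
        converged=converged,
    )


def oligomer_fraction(
    oligomer_bursts: list[Burst],
    monomer_bursts: list[Burst],
    gamma: float,
    mono: MonomerBrightness,
) -> OligomerSummary:
    """Percent of detected monomer-equivalents residing in oligomers.

    Each retained oligomeric burst contributes its apparent size in
    monomer units; each monomeric burst contributes one unit.
    """
    if not oligomer_bursts and not monomer_bursts:
        raise ValueError("no bursts to summarise")
    sizes = np.array(
        [apparent_size(b, gamma, mono) for b in oligomer_bursts], dtype=float
    )
    olig_mass = float(sizes.sum())
    total = olig_mass + len(monomer_bursts)
    if total <= 0:
        raise ValueError("zero total monomer-equivalents")
    return OligomerSummary(
        n_oligomer_bursts=len(oligomer_bursts),
        n_monomer_bursts=len(monomer_bursts),
        mass_fraction=100.0 * olig_mass / total,
        mean_apparent_size=float(sizes.mean()) if sizes.size else 0.0,
    )


@dataclass
class TraceAnalysis:
    """Bundle of everything the burst pipeline derives from one trace."""

    bursts: list[Burst]
    mono: MonomerBrightness
    burst_log: pd.DataFrame
    efficiencies: np.ndarray
    histogram: FretHistogram
    fit: GaussAmpFit | None
    summary: OligomerSummary


def analyze_trace(trace: pd.DataFrame, params: InstrumentParams) -> TraceAnalysis:
    """Run the full burst pipeline on one trace.

    Detect bursts, estimate monomer brightness, filter oligomeric bursts,
    histogram efficiencies, fit the GaussAmp model (skipped when fewer
    than 4 histogram bins are occupied) and summarise the oligomer
    content.
    """
    bursts = detect_bursts(trace, params)
    mono = estimate_monomer_brightness(bursts)
    retained, log = filter_oligomer_bursts(bursts, params.gamma, mono)
    eff = np.array([fret_efficiency(b, params.gamma) for b in retained])
    hist = fret_histogram(eff)
    fit = None
    if np.count_nonzero(hist.counts) >= 4:
        fit = gaussamp_fit(hist)
    monomers = [b for b in bursts if not b.coincident and b.run_length == 1]
    summary = oligomer_fraction(retained, monomers, params.gamma, mono)
    return TraceAnalysis(
        bursts=bursts,
        mono=mono,
        burst_log=log,
        efficiencies=eff,
        histogram=hist,
        fit=fit,
        summary=summary,
    )
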