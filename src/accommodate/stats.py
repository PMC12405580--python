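"""Landscape, convergence, fitting, rate and conservation statistics.

The approximate free-energy landscape over two reaction coordinates is the
Boltzmann-weighted histogram statistic

    dG*(i) = -k_B T ln( P(x_i) / P_max(x) )^2

with P the bin probability and P_max the probability of the most occupied
bin, so the global minimum is exactly 0 and a bin e-fold less likely than
the maximum sits at 2 k_B T.  The squared ratio is implemented exactly as
printed in the source protocol; ``exponent=1`` switches to the conventional
single-power form.  Values are reported in k_B T (the temperature, 300 K by
default, only matters for conversion to absolute units).

Convergence of a simulation is monitored with the pointwise RMSD between the
landscape after time t and the landscape at the first checkpoint:

    Conv(t) = sqrt( sum_ij (dG*(i,j)_t - dG*(i,j)_t0)^2 / N )

over the N bins occupied at both checkpoints.  After Conv(t) plateaus the
sampling is considered converged.

Barrier heights are mapped from mean first-passage times with an Arrhenius
relation, dG_act = k_B T ln(MFPT / tau_attempt), with the attempt time fixed
at one reduced time unit; an experimentally determined reference rate
calibrates the implied real-time scale and is reported alongside.  Barrier
*differences* between two systems therefore equal ln of their MFPT ratio,
independent of the reference rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .containers import ObservableSeries
from .dynamics import EventRecord
from .errors import FitError, NoEventsError, ParameterError



@dataclass
class Landscape2D:
    """Binned 2-D probability / free-energy surface over two observables."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    prob: np.ndarray          # (nx, ny), sums to 1 over occupied bins
    delta_g: np.ndarray       # (nx, ny) in k_B T, NaN on empty bins
    mask: np.ndarray          # True where occupied
    temperature: float = 300.0
    exponent: int = 2

    @property
    def n_occupied(self) -> int:
        return int(self.mask.sum())


@dataclass
class GaussianFit:
    """Single-Gaussian fit of a histogram: counts = A exp(-(x-mean)^2/(2 sd^2))."""

    amplitude: float
    mean: float
    sd: float
    covariance: np.ndarray
    r_squared: float
    ok: bool

    @property
    def stderr(self) -> tuple[float, float, float]:
        se = np.sqrt(np.clip(np.diag(self.covariance), 0, None))
        return float(se[0]), float(se[1]), float(se[2])


@dataclass
class BarrierEstimate:
    """Arrhenius barrier from event statistics."""

    mfpt_tau: float           # mean first-passage time, tau_ru
    mfpt_steps: float         # same, integrator steps
    dg_kbt: float             # point estimate, k_B T
    dg_low: float             # bootstrap 2.5 percentile (NaN if single event)
    dg_high: float            # bootstrap 97.5 percentile
    n_events: int
    reference_rate: float     # 1/s, user supplied
    implied_s_per_tau: float  # real seconds per tau_ru under the calibration
    well_defined: bool        # False when the interval is degenerate

    def __post_init__(self):
        if not (np.isnan(self.dg_low) or self.dg_low <= self.dg_high):
            raise ParameterError("barrier interval low > high")


def _series_values(x) -> np.ndarray:
    return x.values if isinstance(x, ObservableSeries) else np.asarray(x, float)


def free_energy_landscape(
    x,
    y,
    bins: tuple[int, int] = (50, 50),
    temperature: float = 300.0,
    exponent: int = 2,
) -> Landscape2D:
    """Histogram two aligned observable series into a dG* surface (k_B T)."""
    xv, yv = _series_values(x), _series_values(y)
    if len(xv) != len(yv):
        raise ParameterError("x and y series must be aligned in time")
    nx, ny = int(bins[0]), int(bins[1])
    if nx < 2 or ny < 2:
        raise ParameterError("need at least 2 bins per axis")
    if exponent not in (1, 2):
        raise ParameterError("exponent must be 1 or 2")
    counts, xe, ye = np.histogram2d(xv, yv, bins=(nx, ny))
    occupied = counts > 0
    if occupied.sum() <= 1:
        warnings.warn("degenerate landscape: all samples in one bin")
    prob = counts / counts.sum()
    pmax = prob.max()
    dg = np.full_like(prob, np.nan)
    with np.errstate(divide="ignore"):
        dg[occupied] = -exponent * np.log(prob[occupied] / pmax)
    return Landscape2D(xe, ye, prob, dg, occupied,
                       float(temperature), int(exponent))


def landscape_rmsd(a: Landscape2D, b: Landscape2D) -> float:
    """Pointwise RMSD (k_B T) over bins occupied in both landscapes.

    Symmetric; zero iff the two surfaces agree on every shared bin."""
    if a.delta_g.shape != b.delta_g.shape:
        raise ParameterError("landscapes must share binning")
    common = a.mask & b.mask
    n = int(common.sum())
    if n == 0:
        raise ParameterError("no commonly occupied bins: comparison undefined")
    diff = a.delta_g[common] - b.delta_g[common]
    return float(np.sqrt(np.sum(diff ** 2) / n))


def convergence_curve(
    x: ObservableSeries,
    y: ObservableSeries,
    checkpoint_times,
    bins: tuple[int, int] = (50, 50),
    temperature: float = 300.0,
    exponent: int = 2,
) -> ObservableSeries:
    """Conv(t): RMSD of the landscape at each checkpoint against the first.

    All landscapes use a common grid spanning the full data range, so the
    pointwise comparison is well defined; only bins occupied at both
    checkpoints enter (empty bins carry no free-energy estimate).
    """
    checkpoints = np.asarray(checkpoint_times, float)
    if len(checkpoints) < 2:
        raise ParameterError("need at least 2 checkpoint times")
    if np.any(np.diff(checkpoints) <= 0):
        raise ParameterError("checkpoint times must increase")
    nx, ny = int(bins[0]), int(bins[1])
    xr = (float(x.values.min()), float(x.values.max()))
    yr = (float(y.values.min()), float(y.values.max()))
    xe = np.linspace(*xr, nx + 1)
    ye = np.linspace(*yr, ny + 1)

    def landscape_until(t):
        m = x.times <= t
        if m.sum() == 0:
            raise ParameterError(f"no samples before checkpoint {t}")
        counts, _, _ = np.histogram2d(x.values[m], y.values[m], bins=(xe, ye))
        occ = counts > 0
        prob = counts / counts.sum()
        dg = np.full_like(prob, np.nan)
        with np.errstate(divide="ignore"):
            dg[occ] = -exponent * np.log(prob[occ] / prob.max())
        return Landscape2D(xe, ye, prob, dg, occ, temperature, exponent)

    ref = landscape_until(checkpoints[0])
    values = [landscape_rmsd(landscape_until(t), ref) for t in checkpoints]
    return ObservableSeries("Conv", np.array(values), checkpoints, units="kBT")


def fit_gaussian(
    data,
    bins: int = 60,
    p0: tuple[float, float, float] | None = None,
    r2_threshold: float = 0.9,
) -> GaussianFit:
    """Least-squares single-Gaussian fit of binned counts.

    ``data`` is a raw series (histogrammed here) or a (centers, counts) pair.
    The fit is flagged not-ok (e.g. for bimodal input) when R^2 falls below
    ``r2_threshold``.
    """
    if isinstance(data, tuple) and len(data) == 2:
        centers = np.asarray(data[0], float)
        counts = np.asarray(data[1], float)
    else:
        values = _series_values(data)
        counts, edges = np.histogram(values, bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = counts.astype(float)
    if (counts > 0).sum() < 5:
        raise ParameterError("need at least 5 occupied histogram bins")

    def model(xv, a, mu, s):
        return a * np.exp(-((xv - mu) ** 2) / (2.0 * s ** 2))

    if p0 is None:
        w = np.clip(counts, 0, None)
        mu0 = float(np.average(centers, weights=w))
        s0 = float(np.sqrt(np.average((centers - mu0) ** 2, weights=w)))
        p0 = (float(counts.max()), mu0, max(s0, 1e-6))
    try:
        popt, pcov = curve_fit(model, centers, counts, p0=p0, maxfev=10_000)
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}",
                       last_iterate=p0) from exc
    popt[2] = abs(popt[2])
    resid = counts - model(centers, *popt)
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return GaussianFit(float(popt[0]), float(popt[1]), float(popt[2]),
                       pcov, r2, ok=(r2 >= r2_threshold))


def estimate_barrier(
    events: list[EventRecord],
    reference_rate: float,
    dt: float = 0.002,
    tau_map_ns: float = 1.0,
    attempt_time_tau: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> BarrierEstimate:
    """Barrier height (k_B T) from event entry times.

    MFPT is the mean entry time over events; dG_act = ln(MFPT/tau_attempt)
    with a one-reduced-unit attempt time, so barrier differences reduce to
    the log of the MFPT ratio.  ``reference_rate`` (an experimentally
    determined accommodation rate, 1/s) calibrates the implied real-time
    mapping, reported as seconds per tau_ru.  The uncertainty interval is a
    seeded bootstrap (2.5/97.5 percentiles) over events.
    """
    if not events:
        raise NoEventsError("no events: barrier estimate undefined")
    if reference_rate <= 0:
        raise ParameterError("reference rate must be positive")
    entries = np.array([e.entry_time for e in events], float)
    if np.any(entries <= 0):
        raise ParameterError("event entry times must be positive")
    mfpt = float(entries.mean())
    dg = float(np.log(mfpt / attempt_time_tau))
    if len(entries) > 1:
        rng = np.random.default_rng(seed)
        boots = np.log(
            rng.choice(entries, size=(int(n_boot), len(entries))).mean(axis=1)
            / attempt_time_tau
        )
        low, high = (float(np.percentile(boots, 2.5)),
                     float(np.percentile(boots, 97.5)))
        well = True
    else:
        low = high = float("nan")
        well = False
    return BarrierEstimate(
        mfpt_tau=mfpt, mfpt_steps=mfpt / dt, dg_kbt=dg,
        dg_low=low, dg_high=high, n_events=len(entries),
        reference_rate=float(reference_rate),
        implied_s_per_tau=1.0 / (reference_rate * mfpt),
        well_defined=well,
    )


@dataclass
class ColumnConservation:
    """Conservation of one reference-indexed alignment column."""

    position: int             # residue number in the reference sequence
    reference_residue: str
    percent_identity: float   # 0..100, gaps count as mismatches
    alternatives: list[tuple[str, int]]  # non-reference residues by count
    counts: dict              # residue -> count, including the reference


def column_conservation(
    alignment,
    positions,
    reference_id: str,
) -> dict[int, ColumnConservation]:
    """Percent identity of alignment columns, indexed by reference numbering.

    ``alignment`` is a path to an aligned FASTA or a sequence of
    (id, aligned sequence) pairs.  Position k addresses the k-th non-gap
    residue of the reference sequence (1-based).  Gaps in other sequences
    count as mismatches; alternative residues are listed by decreasing
    frequency (gaps excluded from the listing).
    """
    if isinstance(alignment, str):
        from Bio import SeqIO
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(alignment, "fasta")]
    else:
        records = [(str(i), str(s)) for i, s in alignment]
    if not records:
        raise ParameterError("alignment is empty")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ParameterError("sequences are not aligned (unequal lengths)")
    ref = dict(records).get(reference_id)
    if ref is None:
        raise ParameterError(f"reference id {reference_id!r} not in alignment")

    col_of_pos = {}
    resno = 0
    for col, ch in enumerate(ref):
        if ch != "-":
            resno += 1
            col_of_pos[resno] = col
    out: dict[int, ColumnConservation] = {}
    n = len(records)
    for pos in positions:
        pos = int(pos)
        if pos not in col_of_pos:
            raise IndexError(f"position {pos} outside the reference sequence")
        col = col_of_pos[pos]
        column = [s[col] for _, s in records]
        ref_res = ref[col]
        ident = sum(1 for ch in column if ch == ref_res)
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        alts = sorted(
            ((ch, c) for ch, c in counts.items() if ch not in (ref_res, "-")),
            key=lambda kv: (-kv[1], kv[0]),
        )
        out[pos] = ColumnConservation(
            position=pos, reference_residue=ref_res,
            percent_identity=100.0 * ident / n,
            alternatives=alts, counts=counts,
        )
    return out
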