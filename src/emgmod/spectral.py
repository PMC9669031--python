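"""Parameterization of EMG envelope power spectra.

The PSD of each muscle's stride-concatenated envelope is modeled (in
natural-log power) as the sum of an aperiodic Lorentzian background

    L(f) = b - ln(k + f**chi)

and up to ``max_peaks`` Gaussian oscillatory peaks

    G(f) = A * exp(-(f - f_c)**2 / (2 sigma**2)).

Because all cycle-based analyses run on time-normalized data, the
frequency axis is expressed in multiples of the stride frequency 1/T.
Two derived aperiodic parameters summarize the fit: the corrected
offset b* = b - ln(k) (vertical position of the horizontal plateau) and
the corrected knee k* = k**(1/chi) (frequency where the fit bends from
flat to decaying).  Spectral entropy (Shannon entropy of the relative
power over 0..10/T, normalized by ln of the bin count) quantifies the
irregularity of the envelope; 1 corresponds to a flat, white-noise-like
spectrum and 0 to a single spectral line.
"""
from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .containers import CYCLE_SAMPLES, EmgEnvelopeSet, SpectralFit, SpectralPeak

FIT_RANGE = (0.1, 10.0)  # in 1/T units
PEAK_WIDTH_LIMITS = (0.5, 10.0)  # Gaussian sigma bounds, 1/T units
PEAK_THRESHOLD = 2.0  # in SD of the flattened spectrum
MAX_PEAKS = 8


def compute_psd(emg: EmgEnvelopeSet):
    """Periodogram of each muscle's concatenated envelope.

    Returns ``(freqs, psd)`` with ``freqs`` in 1/T units (resolution
    1/(n_strides*T)) and ``psd`` of shape (n_muscles, n_freqs).  The DC
    bin is included; downstream fitting restricts to the 0.1/T-10/T
    band.
    """
    X = emg.data
    n = X.shape[1]
    spec = np.fft.rfft(X, axis=1)
    psd = (np.abs(spec) ** 2) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / CYCLE_SAMPLES)  # cycles per stride
    return freqs, psd


def spectral_entropy(freqs: np.ndarray, psd: np.ndarray, band=(0.0, 10.0)) -> float:
    """Normalized Shannon entropy of the relative power in ``band`` (1/T)."""
    psd = np.asarray(psd, float)
    if np.any(psd < 0):
        raise ValueError("psd must be nonnegative")
    sel = (freqs >= band[0]) & (freqs <= band[1])
    p = psd[sel]
    tot = p.sum()
    if tot == 0:
        raise ValueError("all-zero PSD in band: entropy undefined")
    p = p / tot
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


def _lorentzian(f, b, k, chi):
    return b - np.log(k + f**chi)


def _gaussians(f, params):
    out = np.zeros_like(f)
    for fc, A, sig in params:
        out += A * np.exp(-((f - fc) ** 2) / (2 * sig**2))
    return out


def _fit_aperiodic(f, logp, robust=True):
    bounds = ([-np.inf, 0.0, 0.05], [np.inf, np.inf, 20.0])
    popt = None
    last_err = None
    for guess in ([logp.max(), 1.0, 2.0], [logp.max(), 0.1, 1.0], [logp.mean(), 10.0, 2.0]):
        try:
            popt, _ = curve_fit(
                _lorentzian, f, logp, p0=guess, bounds=bounds, maxfev=20000
            )
            break
        except RuntimeError as err:  # try the next start
            last_err = err
    if popt is None:
        raise RuntimeError(
            f"aperiodic fit failed to converge over {f.size} bins "
            f"(log-power range {logp.min():.1f}..{logp.max():.1f}): {last_err}"
        )
    if robust:
        # refit on the points closest to the first fit: peaks only push
        # the spectrum up, so everything above a low residual quantile
        # is treated as peak-contaminated and dropped
        resid = logp - _lorentzian(f, *popt)
        thresh = np.percentile(resid, 25.0)
        mask = resid <= thresh
        if mask.sum() >= 4:
            try:
                popt, _ = curve_fit(
                    _lorentzian, f[mask], logp[mask], p0=popt, bounds=bounds,
                    maxfev=20000,
                )
            except RuntimeError:
                pass  # keep the full-spectrum fit
    return popt


class SpectralModel:
    """Iterative periodic + aperiodic PSD fit (one spectrum at a time).

    fit(freqs, psd) expects linear power; fitting happens on natural-log
    power over ``fit_range``.  Procedure: robust aperiodic fit ->
    flatten -> iterative Gaussian peak extraction above
    ``peak_threshold`` * SD of the flattened spectrum -> joint Gaussian
    refinement -> aperiodic refit on the peak-removed spectrum.

    Attributes after fit: ``aperiodic_`` (b, k, chi), ``peaks_`` (list of
    SpectralPeak), ``r_squared_``, ``entropy_``.
    """

    def __init__(
        self,
        fit_range=FIT_RANGE,
        peak_width_limits=PEAK_WIDTH_LIMITS,
        peak_threshold=PEAK_THRESHOLD,
        max_peaks=MAX_PEAKS,
    ):
        self.fit_range = fit_range
        self.peak_width_limits = peak_width_limits
        self.peak_threshold = peak_threshold
        self.max_peaks = max_peaks

    def get_params(self, deep=True):
        return {
            "fit_range": self.fit_range,
            "peak_width_limits": self.peak_width_limits,
            "peak_threshold": self.peak_threshold,
            "max_peaks": self.max_peaks,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, freqs: np.ndarray, psd: np.ndarray):
        freqs = np.asarray(freqs, float)
        psd = np.asarray(psd, float)
        lo, hi = self.fit_range
        sel = (freqs >= lo) & (freqs <= hi)
        f, p = freqs[sel], psd[sel]
        if np.any(p <= 0):
            raise ValueError("PSD must be strictly positive over the fit range")
        # relative floor caps the log dynamic range; periodogram valleys
        # of near-periodic envelopes otherwise reach log-power ~ -60
        p = np.maximum(p, p.max() * 1e-10)
        logp = np.log(p)
        wlo, whi = self.peak_width_limits

        def extract_peaks(flat):
            # local maxima by prominence: robust against residual tilt
            # of the flattened spectrum.  The absolute floor guards
            # against "peaks" in numerical noise on spectra the
            # aperiodic form fits exactly.
            prom_thresh = max(self.peak_threshold * flat.std(), 0.05)
            idx, props = find_peaks(flat, prominence=prom_thresh, width=1,
                                    rel_height=0.5)
            df = f[1] - f[0]
            found = [
                (
                    float(f[i]),
                    float(props["prominences"][k]),
                    float(np.clip(props["widths"][k] * df / 2.355, wlo, whi)),
                )
                for k, i in enumerate(idx)
            ]
            found.sort(key=lambda q: -q[1])
            return found[: self.max_peaks]

        def joint_refine(ap, found):
            # refine aperiodic and Gaussian parameters together on the
            # full log spectrum; the sequential estimates are the seed
            def full(x, b, k, chi, *theta):
                prm = [theta[i: i + 3] for i in range(0, len(theta), 3)]
                return _lorentzian(x, b, k, chi) + _gaussians(x, prm)

            p0 = np.concatenate([ap, np.concatenate(found)])
            lb, ub = [-np.inf, 0.0, 0.05], [np.inf, np.inf, 20.0]
            for fc0, _, sig0 in found:
                # keep each center near its guess so no Gaussian can
                # wander off and impersonate the aperiodic background
                lb += [max(lo, fc0 - 1.5 * sig0), 0.0, wlo]
                ub += [min(hi, fc0 + 1.5 * sig0), np.inf, whi]
            lb, ub = np.array(lb), np.array(ub)
            try:
                theta, _ = curve_fit(full, f, logp, p0=p0, bounds=(lb, ub), maxfev=10000)
            except RuntimeError:
                return ap, found
            return theta[:3], [tuple(theta[i: i + 3]) for i in range(3, len(theta), 3)]

        # robust aperiodic fit (tracks the lower envelope of the
        # spectrum), peak extraction on the flattened residual, then a
        # joint refinement of everything
        ap = _fit_aperiodic(f, logp)
        peaks = extract_peaks(logp - _lorentzian(f, *ap))
        if peaks:
            ap, peaks = joint_refine(ap, peaks)
            peaks = [pk for pk in peaks if pk[1] > 0.0]

        model = _lorentzian(f, *ap) + _gaussians(f, peaks)
        ss_res = np.sum((logp - model) ** 2)
        ss_tot = np.sum((logp - logp.mean()) ** 2)
        self.aperiodic_ = tuple(float(v) for v in ap)
        self.peaks_ = [
            SpectralPeak(center=float(fc), power=float(A), bandwidth=float(s))
            for fc, A, s in sorted(peaks, key=lambda q: q[0])
        ]
        self.r_squared_ = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0
        self.entropy_ = spectral_entropy(freqs, psd)
        self.freqs_, self.model_ = f, model
        return self

    def to_result(self) -> SpectralFit:
        b, k, chi = self.aperiodic_
        return SpectralFit(
            offset=b,
            knee=k,
            exponent=chi,
            peaks=list(self.peaks_),
            r_squared=self.r_squared_,
            spectral_entropy=self.entropy_,
            corrected_defined=k > np.finfo(float).eps,
        )


def fit_psd_model(freqs, psd, **settings) -> SpectralFit:
    """Functional wrapper: fit one PSD, return a :class:`SpectralFit`."""
    return SpectralModel(**settings).fit(freqs, psd).to_result()


def fit_envelope_set(emg: EmgEnvelopeSet, **settings) -> list:
    """Fit every muscle of an envelope set; returns one SpectralFit per muscle."""
    freqs, psd = compute_psd(emg)
    return [fit_psd_model(freqs, psd[m], **settings) for m in range(emg.n_muscles)]


def summarize_group_spectra(fits_by_group: dict) -> dict:
    """Group summaries and nonparametric comparisons of spectral measures.

    ``fits_by_group`` maps group label -> list of per-subject lists of
    SpectralFit (one per muscle) or plain lists of SpectralFit.  Returns
    per-group mean +- SD of peak count, peak power, peak bandwidth,
    aperiodic parameters and spectral entropy, plus Wilcoxon rank-sum
    p-values for each measure between the first two groups.
    """
    if len(fits_by_group) < 2:
        raise ValueError("need at least two groups")

    def flatten(entry):
        out = []
        for item in entry:
            out.extend(item if isinstance(item, (list, tuple)) else [item])
        return out

    def measures(fits):
        if len(fits) < 2:
            raise ValueError("insufficient data: group with < 2 fits")
        return {
            "n_peaks": np.array([f.n_peaks for f in fits], float),
            "peak_power": np.array(
                [p.power for f in fits for p in f.peaks] or [np.nan]
            ),
            "peak_bandwidth": np.array(
                [p.bandwidth for f in fits for p in f.peaks] or [np.nan]
            ),
            "offset": np.array([f.offset for f in fits]),
            "corrected_offset": np.array([f.corrected_offset for f in fits]),
            "corrected_knee": np.array([f.corrected_knee for f in fits]),
            "exponent": np.array([f.exponent for f in fits]),
            "spectral_entropy": np.array([f.spectral_entropy for f in fits]),
        }

    def nan_stats(v):
        v = v[~np.isnan(v)]
        if v.size == 0:
            return (np.nan, np.nan)
        return (float(v.mean()), float(v.std()))

    groups = {g: measures(flatten(v)) for g, v in fits_by_group.items()}
    summary = {
        g: {k: nan_stats(v) for k, v in m.items()} for g, m in groups.items()
    }
    ga, gb = list(groups)[:2]
    tests = {}
    for k in groups[ga]:
        a, b = groups[ga][k], groups[gb][k]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size and b.size:
            stat, p = sps.ranksums(a, b)
            tests[k] = {"statistic": float(stat), "p": float(p)}
    return {"summary": summary, "tests": tests, "compared": (ga, gb)}
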