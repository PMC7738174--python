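"""Two-stage ISI coordinate transform, burst phase, and independent components.

For three-spike bursts the two intraburst ISIs are first made
variance-homogeneous across events by the log transform

    v_d = log10(ISI_d - m_d),    d = 1, 2,

where m_d is the x-intercept of the linear fit of the per-event ISI SD against
the per-event ISI mean (events with longer ISIs have proportionally larger
trial-to-trial SD, so v_d has uniform variability).  The standardized pair
(v*_1, v*_2) is then whitened symmetrically (rotate into the principal axes,
scale each axis by the inverse SD, rotate back), giving coordinates (u_1, u_2)
with identity sample covariance.  The burst phase is the polar angle of
(u_1, u_2).

Trial-to-trial residuals (u - event mean) are anisotropic; the principal axis
with the smaller residual variance, at angle theta, defines the approximately
independent components w_1 = u.e(theta), w_2 = u.e(theta + 90 deg); w_1 is the
lower-variance, more informative component shared with 2-spike bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SDMeanFit",
    "ISICoordinates",
    "IndependentComponents",
    "fit_sd_vs_mean",
    "transform_to_u",
    "burst_phase",
    "short_isi_replacement",
    "trial_to_trial_pca",
    "independent_components",
    "steepest_gradient",
    "spike_count_isi_correlation",
    "circular_stats",
]

M_SHRINK_EPS = 0.1  # ms; shrinkage margin when the fitted intercept is too large


def _wrap(angle_deg: float, fold: float) -> float:
    """Wrap into [0, fold), guarding against the float artifact -eps % fold == fold."""
    out = angle_deg % fold
    return 0.0 if out >= fold - 1e-9 else out


@dataclass
class SDMeanFit:
    """Linear fit SD ~ a * (mean - m) of per-event ISI variability."""

    m: float  # x-intercept, ms
    a: float  # slope
    n_events: int
    shrunk: bool = False


def fit_sd_vs_mean(means: np.ndarray, sds: np.ndarray, min_isi: float) -> SDMeanFit:
    """Ordinary least squares of per-event ISI SD on per-event ISI mean.

    The x-intercept is the offset m_d of the log transform.  If the fitted
    intercept is not below the smallest included ISI it is shrunk to
    ``min_isi - 0.1`` ms with a warning (the transform needs ISI_d > m_d).
    A non-positive slope violates the variability model and raises.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if len(means) < 3:
        raise ValueError("need at least 3 events with defined ISI SD")
    slope, intercept = np.polyfit(means, sds, 1)
    if slope <= 0:
        raise ValueError("SD-vs-mean slope is non-positive; variability model violated")
    m = -intercept / slope
    shrunk = False
    if m >= min_isi:
        warnings.warn(
            f"fitted intercept m={m:.2f} ms is not below the smallest ISI "
            f"({min_isi:.2f} ms); shrunk to {min_isi - M_SHRINK_EPS:.2f} ms"
        )
        m = min_isi - M_SHRINK_EPS
        shrunk = True
    return SDMeanFit(m=float(m), a=float(slope), n_events=len(means), shrunk=shrunk)


def fit_sd_vs_mean_from_events(
    isi1: np.ndarray, isi2: np.ndarray, event_ids: np.ndarray, min_bursts: int = 2
) -> tuple[SDMeanFit, SDMeanFit]:
    """Per-dimension SD-vs-mean fits from event-grouped 3-spike burst ISIs.

    Only events with at least ``min_bursts`` bursts contribute (the SD is
    undefined otherwise).
    """
    fits = []
    for isi in (isi1, isi2):
        isi = np.asarray(isi, dtype=float)
        means, sds = [], []
        for ev in np.unique(event_ids):
            x = isi[event_ids == ev]
            if len(x) < min_bursts:
                continue
            means.append(x.mean())
            sds.append(x.std(ddof=1))
        fits.append(fit_sd_vs_mean(np.asarray(means), np.asarray(sds), float(isi.min())))
    return fits[0], fits[1]


@dataclass
class ISICoordinates:
    """Whitened per-burst ISI coordinates and the constants that produced them."""

    isi1: np.ndarray
    isi2: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    phase_deg: np.ndarray
    included: np.ndarray  # boolean mask into the input burst arrays
    fit1: SDMeanFit
    fit2: SDMeanFit
    standardize: tuple[tuple[float, float], tuple[float, float]]  # (mean, sd) of v_d
    axes: np.ndarray  # columns p, q: principal axes of (v*_1, v*_2)
    variances: np.ndarray  # c^2, d^2 along the axes

    @property
    def n(self) -> int:
        return len(self.u1)


def _whiten(v1s: np.ndarray, v2s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric (ZCA) whitening of a standardized 2-D cloud.

    Returns (u (n, 2), axes (2, 2 columns), variances (2,)).
    """
    X = np.column_stack([v1s, v2s])
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    corr = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
    if abs(corr) > 1 - 1e-12:
        raise ValueError("degenerate (perfectly correlated) coordinates; cannot whiten")
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0):
        raise ValueError("non-positive covariance eigenvalue; cannot whiten")
    W = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    U = Xc @ W.T
    return U, evecs, evals


def transform_to_u(
    isi1: np.ndarray,
    isi2: np.ndarray,
    fit1: SDMeanFit,
    fit2: SDMeanFit,
) -> ISICoordinates:
    """Full two-stage transform of 3-spike burst ISIs to whitened (u_1, u_2).

    Bursts with ISI_d <= m_d are excluded (their mask is recorded); use
    :func:`short_isi_replacement` to re-incorporate them.
    """
    isi1 = np.asarray(isi1, dtype=float)
    isi2 = np.asarray(isi2, dtype=float)
    included = (isi1 > fit1.m) & (isi2 > fit2.m)
    if included.sum() < 3:
        raise ValueError("fewer than 3 bursts with ISIs above the offsets m_d")
    v1 = np.log10(isi1[included] - fit1.m)
    v2 = np.log10(isi2[included] - fit2.m)
    stats = []
    vstars = []
    for v in (v1, v2):
        mu, sd = v.mean(), v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance in log-ISI coordinate")
        stats.append((float(mu), float(sd)))
        vstars.append((v - mu) / sd)
    U, axes, variances = _whiten(vstars[0], vstars[1])
    phase = burst_phase(U[:, 0], U[:, 1])
    return ISICoordinates(
        isi1=isi1[included],
        isi2=isi2[included],
        v1=v1,
        v2=v2,
        u1=U[:, 0],
        u2=U[:, 1],
        phase_deg=phase,
        included=included,
        fit1=fit1,
        fit2=fit2,
        standardize=(stats[0], stats[1]),
        axes=axes,
        variances=variances,
    )


def burst_phase(u1: np.ndarray, u2: np.ndarray) -> np.ndarray:
    """Polar angle of (u_1, u_2) in degrees, in [0, 360).

    The origin has no defined phase; such bursts get NaN with a warning.
    """
    u1 = np.atleast_1d(np.asarray(u1, dtype=float))
    u2 = np.atleast_1d(np.asarray(u2, dtype=float))
    phase = np.degrees(np.arctan2(u2, u1)) % 360.0
    at_origin = (u1 == 0) & (u2 == 0)
    if np.any(at_origin):
        warnings.warn("burst at the (u1, u2) origin; phase undefined (NaN)")
        phase = np.where(at_origin, np.nan, phase)
    return phase


def short_isi_replacement(
    isi1: np.ndarray,
    isi2: np.ndarray,
    fit1: SDMeanFit,
    fit2: SDMeanFit,
) -> ISICoordinates:
    """Transform with excluded short-ISI bursts re-incorporated.

    The ISI_d of each excluded burst (ISI_d <= m_d) is replaced with the
    smallest included ISI_d, then the full set is transformed; this tests
    whether dropping very short ISIs biases the phase analyses.
    """
    isi1 = np.asarray(isi1, dtype=float).copy()
    isi2 = np.asarray(isi2, dtype=float).copy()
    inc = (isi1 > fit1.m) & (isi2 > fit2.m)
    if inc.sum() == 0:
        raise ValueError("no included bursts to take replacement ISIs from")
    isi10 = isi1[inc].min()
    isi20 = isi2[inc].min()
    isi1[isi1 <= fit1.m] = isi10
    isi2[isi2 <= fit2.m] = isi20
    return transform_to_u(isi1, isi2, fit1, fit2)


def trial_to_trial_pca(
    u1: np.ndarray,
    u2: np.ndarray,
    event_ids: np.ndarray,
    min_bursts: int = 2,
) -> tuple[float, np.ndarray, bool]:
    """Angle of the smaller-variance axis of within-event residuals.

    Residuals (u - event mean) are pooled over events with at least
    ``min_bursts`` bursts and subjected to PCA.  Returns
    ``(theta_deg in [0, 180), axis variances (small, large), unstable_flag)``;
    the flag is set when the residual distribution is isotropic (variance
    ratio within 1e-6 of 1), in which case theta is arbitrary.
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    event_ids = np.asarray(event_ids)
    res = []
    n_ev_used = 0
    for ev in np.unique(event_ids):
        sel = event_ids == ev
        if sel.sum() < min_bursts:
            continue
        n_ev_used += 1
        res.append(np.column_stack([u1[sel] - u1[sel].mean(), u2[sel] - u2[sel].mean()]))
    if n_ev_used < 2:
        raise ValueError("need at least 2 events with >= 2 bursts each")
    R = np.vstack(res)
    cov = np.cov(R, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)  # ascending: evals[0] is the smaller variance
    small_axis = evecs[:, 0]
    theta = np.degrees(np.arctan2(small_axis[1], small_axis[0])) % 180.0
    unstable = bool(evals[1] / evals[0] < 1 + 1e-6)
    if unstable:
        warnings.warn("isotropic trial-to-trial residuals; theta is unstable")
    return float(theta), evals, unstable


@dataclass
class IndependentComponents:
    """Rotation of (u_1, u_2) onto the trial-to-trial principal axes."""

    theta_deg: float
    w1: np.ndarray
    w2: np.ndarray
    axis_variances: np.ndarray  # residual variances along (w1, w2)


def independent_components(
    u1: np.ndarray, u2: np.ndarray, theta_deg: float, axis_variances=None
) -> IndependentComponents:
    """w_1 = u_1 cos(theta) + u_2 sin(theta); w_2 the orthogonal component."""
    th = np.deg2rad(theta_deg)
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    w1 = u1 * np.cos(th) + u2 * np.sin(th)
    w2 = u1 * np.cos(th + np.pi / 2) + u2 * np.sin(th + np.pi / 2)
    return IndependentComponents(
        theta_deg=float(theta_deg),
        w1=w1,
        w2=w2,
        axis_variances=np.asarray(axis_variances) if axis_variances is not None else None,
    )


def phase_sets(
    phases_deg: np.ndarray, theta_deg: float, half_width: float
) -> dict[str, np.ndarray]:
    """Boolean masks for bursts with phase near theta, theta+90, +180, +270.

    ``half_width`` 15 deg gives the narrow deviation groups; 45 deg gives the
    quadrant partition used for the projection features (the four masks then
    cover every burst exactly once).
    """
    phi = np.asarray(phases_deg, dtype=float)
    out = {}
    for name, center in (
        ("w1_plus", theta_deg),
        ("w2_plus", theta_deg + 90),
        ("w1_minus", theta_deg + 180),
        ("w2_minus", theta_deg + 270),
    ):
        d = (phi - center + 180.0) % 360.0 - 180.0  # signed angular distance
        out[name] = (d >= -half_width) & (d < half_width)
    return out


def steepest_gradient(
    m_event: np.ndarray, u1_event: np.ndarray, u2_event: np.ndarray
) -> tuple[float, np.ndarray]:
    """Direction of the steepest gradient of the 2-spike ISI on the u-plane.

    Fits m^(j) = a0 + a1 * u1bar^(j) + a2 * u2bar^(j) by least squares over
    events containing both burst types; returns (direction deg in [0, 360),
    coefficients (a0, a1, a2)).
    """
    m = np.asarray(m_event, dtype=float)
    u1 = np.asarray(u1_event, dtype=float)
    u2 = np.asarray(u2_event, dtype=float)
    if len(m) < 4:
        raise ValueError("need at least 4 events with both 2- and 3-spike bursts")
    X = np.column_stack([np.ones_like(m), u1, u2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design; events do not span the u-plane")
    coef, *_ = np.linalg.lstsq(X, m, rcond=None)
    direction = _wrap(np.degrees(np.arctan2(coef[2], coef[1])), 360.0)
    return float(direction), coef


def spike_count_isi_correlation(n_event: np.ndarray, m_event: np.ndarray) -> float:
    """Pearson correlation across events between the mean spike count and the
    mean 2-spike ISI.  Returns NaN (with a warning) when either variable has
    zero variance.
    """
    n = np.asarray(n_event, dtype=float)
    m = np.asarray(m_event, dtype=float)
    if len(n) < 3:
        raise ValueError("need at least 3 events")
    if n.std() == 0 or m.std() == 0:
        warnings.warn("zero variance; correlation undefined")
        return float("nan")
    return float(np.corrcoef(n, m)[0, 1])


def circular_stats(angles_deg: np.ndarray, fold_deg: int = 360) -> tuple[float, float]:
    """Circular mean and circular SD of angles, in degrees.

    With ``fold_deg=180`` (axial data) angles are doubled before vector
    averaging and the mean is folded back.  The circular SD is
    sqrt(-2 ln Rbar) (also halved for axial data).  A near-zero resultant
    raises, as the mean is then undefined.
    """
    a = np.asarray(angles_deg, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 angles")
    if fold_deg not in (180, 360):
        raise ValueError("fold_deg must be 180 or 360")
    mult = 360 // fold_deg
    z = np.exp(1j * np.deg2rad(a * mult))
    zbar = z.mean()
    rbar = np.abs(zbar)
    if rbar < 1e-9:
        raise ValueError("resultant length ~ 0; circular mean undefined")
    mean = _wrap(np.degrees(np.angle(zbar)) / mult, fold_deg)
    sd = np.degrees(np.sqrt(-2.0 * np.log(rbar))) / mult
    return float(mean), float(sd)
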