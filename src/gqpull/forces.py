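"""Spring-force reconstruction and decomposition for constant-velocity pulls.

The pull is a moving harmonic distance restraint between two anchors (the
geometric centers of C2/C4/C6 of the two terminal thymines): the restraint
center moves as ``c(t) = d0 + v t`` and the instantaneous spring force on
the anchor distance ``d`` is ``F = k (c(t) - d)``.  Internally forces are
expressed in piconewton via

    1 kJ mol^-1 nm^-1 = 1.660539 pN

(10^21 / N_A with the CODATA Avogadro constant), which makes outputs
bit-reproducible.  A positive force stretches the anchors apart;
compressive episodes are negative and ``|F|`` is used for averages.

The decomposition relative to the stem refers to the average quartet
plane: beta is the out-of-plane angle of the force (0 for an in-plane
force, +/-90 for a force along the normal), and

    F_horizontal = F cos(beta),   F_vertical = F sin(beta),

with the vertical-to-horizontal ratio equal to tan(beta).  The force-edge
overlap feo = (|F.u_wc| - |F.u_h|)/|F| measures whether the force aligns
better with the Watson-Crick or the Hoogsteen H-bond edge of a designated
guanine; positive means better alignment with the Watson-Crick edge.

Rupture force: maximum of the running average of |F| (2 ns window by
default) over windows lying wholly before the first stem-altering
unfolding event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import QuartetPlane

#: pN per kJ mol^-1 nm^-1 (10^21 / Avogadro constant).
PN_PER_KJ_MOL_NM = 1.660539

#: Default rupture/transition averaging window, ns.
DEFAULT_WINDOW_NS = 2.0


@dataclass(frozen=True)
class PullingSchedule:
    """Moving harmonic restraint: c(t) = d0 + v t.

    Parameters
    ----------
    force_constant : kJ mol^-1 nm^-2 (default 180)
    pull_speed : nm us^-1 (default 5.4)
    d0 : initial restraint center, nm
    anchors : optional pair of anchor atom groups, each a tuple of
        (ResidueId, atom name); informational, used by IO to resolve the
        anchor distance from coordinates.
    """

    force_constant: float = 180.0
    pull_speed: float = 5.4
    d0: float = 0.0
    anchors: tuple | None = None

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if self.pull_speed < 0:
            raise ValueError("pull speed must be non-negative")

    def center(self, time_ns: np.ndarray | float) -> np.ndarray | float:
        """Restraint center (nm) at the given time(s) in ns."""
        return self.d0 + self.pull_speed * 1e-3 * np.asarray(time_ns, float)


@dataclass
class ForceSeries:
    """Time series of the pulling coordinate and reconstructed spring force.

    ``force_pN`` is the signed scalar spring force; ``force_vec`` (optional)
    is the force vector along the anchor-1 -> anchor-2 line in pN.
    """

    time_ns: np.ndarray
    distance_nm: np.ndarray
    center_nm: np.ndarray
    force_pN: np.ndarray
    force_vec: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, float)
        self.distance_nm = np.asarray(self.distance_nm, float)
        self.center_nm = np.asarray(self.center_nm, float)
        self.force_pN = np.asarray(self.force_pN, float)
        n = len(self.time_ns)
        for arr in (self.distance_nm, self.center_nm, self.force_pN):
            if len(arr) != n:
                raise ValueError("force series columns have unequal lengths")
        if np.any(np.diff(self.time_ns) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.force_pN)

    @property
    def dt(self) -> float:
        steps = np.diff(self.time_ns)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("force series is not uniformly sampled")
        return float(steps[0]) if steps.size else 0.0


def spring_force(
    time_ns: np.ndarray,
    distance_nm: np.ndarray,
    schedule: PullingSchedule,
    anchor_direction: np.ndarray | None = None,
) -> ForceSeries:
    """Reconstruct the spring force from the anchor-distance series.

    ``anchor_direction`` (optional, shape (n, 3) or (3,)) gives the unit
    vector from anchor 1 to anchor 2 per sample, in which case the force
    vector is filled in; otherwise only the scalar is produced.
    """
    t = np.asarray(time_ns, float)
    d = np.asarray(distance_nm, float)
    c = np.asarray(schedule.center(t), float)
    f = schedule.force_constant * (c - d) * PN_PER_KJ_MOL_NM
    vec = None
    if anchor_direction is not None:
        u = np.atleast_2d(np.asarray(anchor_direction, float))
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        if u.shape[0] == 1:
            u = np.broadcast_to(u, (len(t), 3))
        vec = f[:, None] * u
    return ForceSeries(
        time_ns=t, distance_nm=d, center_nm=c, force_pN=f, force_vec=vec
    )


def average_plane_normal(planes: list[QuartetPlane]) -> np.ndarray:
    """Mean of co-oriented quartet normals, renormalised.

    Normals are assumed co-oriented 5'->3' already (frame geometry does
    this); the first normal's orientation is used to resolve any stragglers.
    """
    ref = planes[0].normal
    n = np.zeros(3)
    for p in planes:
        n += p.normal if np.dot(p.normal, ref) >= 0 else -p.normal
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("average plane normal vanishes")
    return n / norm


def out_of_plane_angle(
    force_vec: np.ndarray, planes: list[QuartetPlane] | np.ndarray
) -> float:
    """Out-of-plane angle beta (degrees) of the force, in [-90, 90].

    ``planes`` may be a list of fitted quartet planes or a ready-made unit
    normal.  The sign follows the 5'->3' normal orientation.  Returns NaN
    for a vanishing force (the angle is undefined, not an error: the spring
    force can cross zero mid-trajectory).
    """
    f = np.asarray(force_vec, float)
    fn = np.linalg.norm(f)
    if fn < 1e-12:
        return float("nan")
    if isinstance(planes, (list, tuple)):
        normal = average_plane_normal(list(planes))
    else:
        normal = np.asarray(planes, float)
        normal = normal / np.linalg.norm(normal)
    s = float(np.clip(np.dot(f / fn, normal), -1.0, 1.0))
    return float(np.degrees(np.arcsin(s)))


@dataclass(frozen=True)
class ForceDecomposition:
    """In-plane / out-of-plane split of the pulling force."""

    beta_deg: float
    f_horizontal: float
    f_vertical: float
    vh_ratio: float


def decompose(force_magnitude: float, beta_deg: float) -> ForceDecomposition:
    """F_h = F cos(beta), F_v = F sin(beta); vh_ratio = tan(beta).

    ``vh_ratio`` is NaN where |beta| = 90 (horizontal component vanishes).
    """
    if force_magnitude < 0:
        raise ValueError("force magnitude must be non-negative")
    b = np.radians(beta_deg)
    fh = force_magnitude * np.cos(b)
    fv = force_magnitude * np.sin(b)
    ratio = np.tan(b) if abs(abs(beta_deg) - 90.0) > 1e-12 else float("nan")
    return ForceDecomposition(
        beta_deg=float(beta_deg),
        f_horizontal=float(fh),
        f_vertical=float(fv),
        vh_ratio=float(ratio),
    )


@dataclass(frozen=True)
class EdgeVectors:
    """Unit vectors along the WC- and Hoogsteen-edge H-bond directions."""

    u_wc: np.ndarray
    u_h: np.ndarray


def _mean_unit(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    u = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
    n = np.linalg.norm(u)
    if n < 1e-12:
        raise ValueError("edge H-bond vectors are anti-parallel")
    return u / n


def edge_unit_vectors(
    g_atoms: dict[str, np.ndarray],
    wc_partner_atoms: dict[str, np.ndarray],
    h_partner_atoms: dict[str, np.ndarray],
) -> EdgeVectors:
    """H-bond edge directions of a designated guanine in its quartet.

    The guanine donates N1-H...O6' and N2-H...N7' to its Watson-Crick-side
    partner (``wc_partner_atoms``) and accepts O6...H-N1'' and N7...H-N2''
    from its Hoogsteen-side partner (``h_partner_atoms``).  Each edge
    vector is the normalised mean of its two H-bond unit vectors; overall
    sign is irrelevant downstream (absolute dot products are used).
    """
    try:
        u_wc = _mean_unit(
            wc_partner_atoms["O6"] - g_atoms["N1"],
            wc_partner_atoms["N7"] - g_atoms["N2"],
        )
        u_h = _mean_unit(
            h_partner_atoms["N1"] - g_atoms["O6"],
            h_partner_atoms["N2"] - g_atoms["N7"],
        )
    except KeyError as exc:
        raise KeyError(f"missing H-bond edge atom {exc} on quartet partner") from exc
    return EdgeVectors(u_wc=u_wc, u_h=u_h)


def force_edge_overlap(force_vec: np.ndarray, edges: EdgeVectors) -> float:
    """feo = (|F.u_wc| - |F.u_h|) / |F|, in [-1, 1].

    Positive: the pulling force aligns better with the Watson-Crick edge;
    negative: better with the Hoogsteen edge.  NaN for zero force.
    """
    f = np.asarray(force_vec, float)
    fn = np.linalg.norm(f)
    if fn < 1e-12:
        return float("nan")
    return float((abs(f @ edges.u_wc) - abs(f @ edges.u_h)) / fn)


# ---------------------------------------------------------------------------
# windowed-force extraction


def _window_length(dt: float, window_ns: float) -> int:
    """Number of samples spanning the window: (m - 1) dt <= window."""
    if dt <= 0:
        return 1
    return int(np.floor(window_ns / dt + 1e-9)) + 1


def running_mean_force(series: ForceSeries, window_ns: float) -> tuple[np.ndarray, np.ndarray]:
    """Running mean of |F| over contiguous sample windows of the given span.

    Returns (window end times, window means); window i covers samples
    [i, i + m) with m chosen so the window spans ``window_ns``.
    """
    mag = series.magnitude
    m = min(_window_length(series.dt, window_ns), len(mag))
    csum = np.concatenate([[0.0], np.cumsum(mag)])
    means = (csum[m:] - csum[:-m]) / m
    end_times = series.time_ns[m - 1:]
    return end_times, means


def rupture_force(
    series: ForceSeries,
    first_event_time: float,
    window_ns: float = DEFAULT_WINDOW_NS,
) -> float:
    """Maximum windowed-average |F| ahead of the first unfolding event.

    Considers every window position lying wholly inside
    [t_start, first_event_time].
    """
    if first_event_time < series.time_ns[0]:
        raise ValueError("first event precedes the first force sample")
    span = first_event_time - series.time_ns[0]
    if window_ns > span:
        raise ValueError(
            f"averaging window ({window_ns} ns) exceeds the pre-event span "
            f"({span:.6g} ns)"
        )
    end_times, means = running_mean_force(series, window_ns)
    valid = end_times <= first_event_time + 1e-12
    if not valid.any():
        raise ValueError("no complete averaging window before the event")
    return float(means[valid].max())


def transition_forces(
    series: ForceSeries,
    event_times: np.ndarray,
    window_ns: float = DEFAULT_WINDOW_NS,
) -> np.ndarray:
    """Average |F| over the trailing window ending at each event time.

    For each event, the mean of |F| over samples in
    [t_event - window, t_event]; a window reaching past the start of the
    trajectory is truncated there (with a warning).
    """
    times = np.asarray(event_times, float)
    if np.any(np.diff(times) < 0):
        raise ValueError("event times must be sorted")
    out = np.empty(len(times))
    for i, te in enumerate(times):
        t0 = te - window_ns
        if t0 < series.time_ns[0] - 1e-12:
            warnings.warn(
                f"transition window at t={te:g} ns truncated at trajectory start",
                stacklevel=2,
            )
            t0 = series.time_ns[0]
        mask = (series.time_ns >= t0 - 1e-12) & (series.time_ns <= te + 1e-12)
        if not mask.any():
            raise ValueError(f"no force samples in window ending at {te:g} ns")
        out[i] = series.magnitude[mask].mean()
    return out
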