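"""Best-fit (Kabsch) superposition and C-alpha RMSD time series.

RMSD is unweighted (uniform masses): the analyses downstream are C-alpha
only.  Chirality is preserved by correcting the sign of the smallest
singular value, so the returned rotation is always proper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Selection, Trajectory, resolve_selection


class DegenerateGeometryError(ValueError):
    """Point set is rank-deficient (collinear/coincident) — no unique fit."""


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to
    ``reference`` over all proper rigid transforms.

    Raises
    ------
    ValueError
        if the point sets differ in shape or have fewer than 3 points.
    DegenerateGeometryError
        if either centred point set has rank < 2 (collinear input), in
        which case the optimal rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need N x 3 arrays with N >= 3")

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    for label, pts in (("mobile", mob_c), ("reference", ref_c)):
        rank = np.linalg.matrix_rank(pts, tol=1e-8 * max(1.0, np.abs(pts).max()))
        if rank < 2:
            raise DegenerateGeometryError(
                f"{label} point set has rank {rank} (< 2): degenerate geometry"
            )

    H = mob_c.T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    translation = reference.mean(axis=0) - mobile.mean(axis=0) @ R.T
    diff = mob_c @ R.T - ref_c
    rmsd = float(np.sqrt((diff**2).sum() / mobile.shape[0]))
    return R, translation, rmsd


@dataclass
class RMSDSeries:
    """RMSD (A) per frame against a reference frame of the trajectory."""

    times_ns: np.ndarray
    values_A: np.ndarray
    selection: Selection
    reference_frame: int
    fit_selection: Selection | None = field(default=None)

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.values_A = np.asarray(self.values_A, dtype=float)
        if self.times_ns.shape != self.values_A.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values_A < -1e-12):
            raise ValueError("negative RMSD")


def rmsd_series(
    traj: Trajectory,
    sel: Selection | str = Selection("name CA"),
    reference_frame: int = 0,
    fit_sel: Selection | str | None = None,
) -> RMSDSeries:
    """Best-fit RMSD of ``sel`` per frame relative to ``reference_frame``.

    By default the fit and report selections coincide.  Passing ``fit_sel``
    superposes on one atom set (e.g. the whole complex) while reporting the
    RMSD over another (e.g. the inhibitor only).
    """
    sel = sel if isinstance(sel, Selection) else Selection(sel)
    report_idx = resolve_selection(traj.topology, sel)
    if report_idx.size == 0:
        raise ValueError(f"empty selection {sel.expression!r}")
    if fit_sel is None:
        fit_idx = report_idx
    else:
        fit_sel = fit_sel if isinstance(fit_sel, Selection) else Selection(fit_sel)
        fit_idx = resolve_selection(traj.topology, fit_sel)
        if fit_idx.size == 0:
            raise ValueError(f"empty fit selection {fit_sel.expression!r}")

    ref = traj.frames[reference_frame].coords
    ref_fit = ref[fit_idx]
    ref_rep = ref[report_idx]
    values = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        R, t, _ = kabsch_superpose(frame.coords[fit_idx], ref_fit)
        moved = frame.coords[report_idx] @ R.T + t
        values[k] = np.sqrt(((moved - ref_rep) ** 2).sum() / report_idx.size)
    return RMSDSeries(
        times_ns=traj.times_ns,
        values_A=values,
        selection=sel,
        reference_frame=reference_frame,
        fit_selection=fit_sel if fit_sel is not None else None,
    )


def trim_equilibration(
    times_ns: np.ndarray, *series: np.ndarray, drop_ns: float = 25.0
) -> tuple[np.ndarray, ...]:
    """Drop the initial equilibration window from one or more time series.

    Retains samples with ``time >= drop_ns``.  Every time-averaged
    statistic in the pipeline consumes trimmed series; 25 ns is the
    default conservative equilibration allowance.
    """
    if drop_ns < 0:
        raise ValueError("drop_ns must be >= 0")
    times_ns = np.asarray(times_ns, dtype=float)
    keep = times_ns >= drop_ns
    if not keep.any():
        raise ValueError(
            f"empty analysis window: drop_ns={drop_ns} >= span {times_ns.max() if times_ns.size else 0}"
        )
    out = [times_ns[keep]]
    for s in series:
        s = np.asarray(s)
        if s.shape[0] != times_ns.shape[0]:
            raise ValueError("series length does not match times")
        out.append(s[keep])
    return tuple(out)


def trim_frames(traj: Trajectory, drop_ns: float = 25.0) -> np.ndarray:
    """Indices of trajectory frames inside the analysis window."""
    times = traj.times_ns
    keep = np.nonzero(times >= drop_ns)[0]
    if keep.size == 0:
        raise ValueError("empty analysis window")
    return keep
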