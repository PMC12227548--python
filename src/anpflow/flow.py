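"""Tissue-flow quantification: PIV surrogate, domain binning, left-right
symmetrisation and axis profiles.

The PIV surrogate is single-pass normalized cross-correlation per
interrogation window with a 3-point Gaussian subpixel peak fit — the
commodity part of PIV; the pipeline equally accepts externally computed
velocity fields from CSV.

Domain averaging follows the experimental protocol: velocities averaged in
boxes with sides of 30 µm spanning from the origin along the lateral and
AP axes, over a 15-min window.

Left-right symmetrisation respects vector parity about the midline:
``u`` (ML) is odd, ``v`` (AP) even in x, so

    u_sym(x, y) = (u(x, y) − u(−x, y)) / 2
    v_sym(x, y) = (v(x, y) + v(−x, y)) / 2.
"""

from __future__ import annotations

import warnings

import numpy as np

from .fields import GridSpec, TrackSet, VelocityField

__all__ = ["piv_block_match", "bin_and_average", "symmetrise",
           "axis_profiles"]


def _subpixel(c3: np.ndarray) -> float:
    """3-point Gaussian peak interpolation; parabolic fallback."""
    cm, c0, cp = c3
    if cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        den = lm - 2 * l0 + lp
        if den < 0:
            return float(0.5 * (lm - lp) / den)
    den = cm - 2 * c0 + cp
    if den < 0:
        return float(0.5 * (cm - cp) / den)
    return 0.0


def piv_block_match(frame_a: np.ndarray, frame_b: np.ndarray,
                    window_px: int = 32, step_px: int | None = None,
                    dt: float = 1.0, pixel_size: float = 1.0,
                    max_disp: int | None = None) -> VelocityField:
    """Displacement field between two frames by windowed cross-correlation.

    Parameters
    ----------
    window_px : interrogation window side (>= 8 px).
    step_px : window spacing; defaults to window_px // 2.
    dt : frame interval (min); velocities are displacement/dt.
    pixel_size : µm per pixel.
    max_disp : largest displacement searched; defaults to
        window_px // 4 + 2, so displacements up to a quarter window sit
        strictly inside the search range (a peak on the search boundary
        cannot be refined and biases toward the range edge).

    Flat (zero-variance) windows produce masked vectors.
    """
    from skimage.feature import match_template

    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share shape")
    if window_px < 8:
        raise ValueError("window must be >= 8 px")
    step = step_px or window_px // 2
    md = max_disp or window_px // 4 + 2
    half = window_px // 2
    t_half = half - md                 # template smaller than the window,
    if t_half < 2:                     # so no content is lost at any lag
        raise ValueError("window too small for the search range")

    cy = np.arange(half, a.shape[0] - half + 1, step)
    cx = np.arange(half, a.shape[1] - half + 1, step)
    u = np.zeros((cy.size, cx.size))
    v = np.zeros((cy.size, cx.size))
    mask = np.zeros((cy.size, cx.size), dtype=bool)
    for j, yc in enumerate(cy):
        for i, xc in enumerate(cx):
            tmpl = a[yc - t_half:yc + t_half, xc - t_half:xc + t_half]
            wb = b[yc - half:yc + half, xc - half:xc + half]
            if tmpl.std() < 1e-12 or wb.std() < 1e-12:
                continue
            c = match_template(wb, tmpl)    # (2md+1)² NCC lag map
            pj, pi = np.unravel_index(np.argmax(c), c.shape)
            dyy = pj - md
            dxx = pi - md
            sub_y = sub_x = 0.0
            # a perfect match (NCC = 1) is an exactly integer displacement;
            # subpixel refinement would only add noise there
            if c[pj, pi] <= 1.0 - 1e-9:
                if 0 < pj < c.shape[0] - 1:
                    sub_y = _subpixel(c[pj - 1:pj + 2, pi])
                if 0 < pi < c.shape[1] - 1:
                    sub_x = _subpixel(c[pj, pi - 1:pi + 2])
            u[j, i] = (dxx + sub_x) * pixel_size / dt
            v[j, i] = (dyy + sub_y) * pixel_size / dt
            mask[j, i] = True
    grid = GridSpec(cx * pixel_size, cy * pixel_size)
    return VelocityField(grid, u, v, mask)


def _track_velocities(tracks: TrackSet):
    """Per-sample central-difference velocities of a track set."""
    rows = []  # (t, x, y, u, v)
    for tr in tracks:
        if tr.t.size < 2:
            continue
        u = np.gradient(tr.x, tr.t)
        v = np.gradient(tr.y, tr.t)
        rows.append(np.column_stack([tr.t, tr.x, tr.y, u, v]))
    if not rows:
        return np.empty((0, 5))
    return np.vstack(rows)


def bin_and_average(source, box: float = 30.0, window: float = 15.0,
                    time: float | None = None,
                    grid: GridSpec | None = None) -> VelocityField:
    """Average velocities in boxes of side ``box`` µm over a time window.

    ``source`` is a list of :class:`VelocityField` or a :class:`TrackSet`.
    Boxes span from the origin along the lateral and AP axes; samples with
    timestamp in ``[time − window/2, time + window/2]`` contribute (all
    samples if ``time`` is None).  Empty boxes are masked.
    """
    if box <= 0:
        raise ValueError("box must be > 0")
    if isinstance(source, TrackSet):
        data = _track_velocities(source)
        if time is not None:
            sel = np.abs(data[:, 0] - time) <= window / 2
            data = data[sel]
        xs, ys, us, vs = data[:, 1], data[:, 2], data[:, 3], data[:, 4]
    else:
        fields = list(source)
        if time is not None:
            fields = [f for f in fields
                      if abs(f.time - time) <= window / 2 / 60.0
                      or abs(f.time - time) <= window / 2]
        if not fields:
            raise ValueError("no fields inside the averaging window")
        xs, ys, us, vs = [], [], [], []
        for f in fields:
            X, Y = f.grid.meshgrid()
            xs.append(X[f.mask])
            ys.append(Y[f.mask])
            us.append(f.u[f.mask])
            vs.append(f.v[f.mask])
        xs = np.concatenate(xs)
        ys = np.concatenate(ys)
        us = np.concatenate(us)
        vs = np.concatenate(vs)

    if grid is None:
        # box centres spanning from the origin outwards
        def centers(lo, hi):
            n_neg = int(np.ceil(max(-lo, 0) / box))
            n_pos = int(np.ceil(max(hi, 0) / box))
            if n_neg + n_pos < 2:      # degenerate: pad to a 2-box grid
                n_pos += 2 - (n_neg + n_pos)
            return (np.arange(-n_neg, n_pos) + 0.5) * box
        if xs.size == 0:
            raise ValueError("no velocity samples to bin")
        grid = GridSpec(centers(xs.min(), xs.max()),
                        centers(ys.min(), ys.max()))
    gx, gy = grid.x, grid.y
    ix = np.round((xs - gx[0]) / box).astype(int)
    iy = np.round((ys - gy[0]) / box).astype(int)
    ok = (ix >= 0) & (ix < gx.size) & (iy >= 0) & (iy < gy.size)
    shape = (gy.size, gx.size)
    count = np.zeros(shape)
    su = np.zeros(shape)
    sv = np.zeros(shape)
    np.add.at(count, (iy[ok], ix[ok]), 1)
    np.add.at(su, (iy[ok], ix[ok]), us[ok])
    np.add.at(sv, (iy[ok], ix[ok]), vs[ok])
    mask = count > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(mask, su / np.where(mask, count, 1), 0.0)
        v = np.where(mask, sv / np.where(mask, count, 1), 0.0)
    return VelocityField(grid, u, v, mask,
                         time=np.nan if time is None else time)


def symmetrise(field: VelocityField) -> VelocityField:
    """Left-right (midline) symmetrisation respecting vector parity.

    The output satisfies ``u`` odd and ``v`` even in x exactly.  A linear,
    idempotent projection; requires (or resamples to) a grid symmetric
    about x = 0.
    """
    x = field.x
    if not np.allclose(x + x[::-1], 0, atol=1e-6 * max(1, np.ptp(x))):
        warnings.warn("grid not symmetric about x = 0; resampling",
                      stacklevel=2)
        half = min(-x[0], x[-1])
        n = x.size
        xs = np.linspace(-half, half, n if n % 2 == 1 else n + 1)
        from scipy.interpolate import RegularGridInterpolator
        giu = RegularGridInterpolator((field.y, x), field.u,
                                      bounds_error=False)
        giv = RegularGridInterpolator((field.y, x), field.v,
                                      bounds_error=False)
        X, Y = np.meshgrid(xs, field.y)
        pts = np.column_stack([Y.ravel(), X.ravel()])
        u = giu(pts).reshape(X.shape)
        v = giv(pts).reshape(X.shape)
        m = np.isfinite(u) & np.isfinite(v)
        u = np.where(m, u, 0.0)
        v = np.where(m, v, 0.0)
        field = VelocityField(GridSpec(xs, field.y), u, v, m, field.time)
        x = field.x
    u_ref = field.u[:, ::-1]       # u(−x, y)
    v_ref = field.v[:, ::-1]
    m = field.mask & field.mask[:, ::-1]
    u_sym = np.where(m, 0.5 * (field.u - u_ref), 0.0)
    v_sym = np.where(m, 0.5 * (field.v + v_ref), 0.0)
    return VelocityField(field.grid, u_sym, v_sym, m, field.time)


def axis_profiles(field: VelocityField, transect_y: float,
                  anterior_positive: bool = False
                  ) -> tuple[np.ndarray, np.ndarray]:
    """AP and ML profiles of a flow field.

    Returns ``(ap_profile, ml_profile)``: the AP profile is ``v`` along the
    midline column (x = 0) against y (0 = tissue front); the ML profile is
    the speed along the transect row at ``transect_y`` against x (0 =
    midline).  With ``anterior_positive=True`` the AP profile is exported
    in the plotting convention (positive = anterior-directed flow), i.e.
    sign-flipped; the raw convention is positive = posterior.
    """
    x, y = field.x, field.y
    if not (y[0] <= transect_y <= y[-1]):
        raise ValueError("transect outside grid")
    imid = int(np.argmin(np.abs(x)))
    if abs(x[imid]) > (x[1] - x[0]) / 2 + 1e-9:
        raise ValueError("no midline column near x = 0")
    ap = field.v[:, imid].copy()
    if anterior_positive:
        ap = -ap
    ap_profile = np.column_stack([y, ap])
    irow = int(np.argmin(np.abs(y - transect_y)))
    ml = np.hypot(field.u[irow, :], field.v[irow, :])
    ml_profile = np.column_stack([x, ml])
    return ap_profile, ml_profile
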