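"""Compiled inner loops for particle propagation.

These functions operate on raw arrays and are wrapped by the public API in
:mod:`ldpf.tracers`, :mod:`ldpf.coupled` and :mod:`ldpf.stats`.  They are
single-threaded on purpose: reproducibility from a single integer seed is a
hard requirement of every simulation entry point.

Error codes returned by the stepping kernels (0 = success):

* 1 — particle overlap below the hard floor ``1e-6 * sigma``
* 2 — single-step displacement exceeding half the box
"""

import numpy as np
from numba import njit

OK = 0
ERR_OVERLAP = 1
ERR_STEP_TOO_LARGE = 2


@njit(cache=True, inline="always")
def _bilinear(grid, x, y, inv_dx, L):
    """Periodic bilinear interpolation of ``grid`` at position ``(x, y)``.

    Grid values live on nodes ``(i*dx, j*dx)``; indices wrap around.
    """
    gx = x * inv_dx
    gy = y * inv_dx
    fgx = np.floor(gx)
    fgy = np.floor(gy)
    fx = gx - fgx
    fy = gy - fgy
    i0 = int(fgx) % L
    j0 = int(fgy) % L
    i1 = (i0 + 1) % L
    j1 = (j0 + 1) % L
    return (grid[i0, j0] * (1.0 - fx) * (1.0 - fy)
            + grid[i1, j0] * fx * (1.0 - fy)
            + grid[i0, j1] * (1.0 - fx) * fy
            + grid[i1, j1] * fx * fy)


@njit(cache=True)
def _lj_forces(pos, forces, box, eps, sigma, rcut, head, nxt, ncell):
    """Truncated (unshifted) Lennard-Jones forces via a linked-cell list.

    ``ncell < 3`` means the cell decomposition is degenerate; the caller must
    have picked brute force instead.  Pairs are visited twice (i->j and j->i)
    which keeps the loop branch-free.
    """
    n = pos.shape[0]
    cell_size = box / ncell
    rcut2 = rcut * rcut
    floor2 = (1e-6 * sigma) ** 2
    sig2 = sigma * sigma
    for c in range(ncell * ncell):
        head[c] = -1
    for i in range(n):
        cx = int(pos[i, 0] / cell_size) % ncell
        cy = int(pos[i, 1] / cell_size) % ncell
        c = cx * ncell + cy
        nxt[i] = head[c]
        head[c] = i
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        cx = int(xi / cell_size) % ncell
        cy = int(yi / cell_size) % ncell
        for ox in range(-1, 2):
            ccx = (cx + ox) % ncell
            for oy in range(-1, 2):
                c = ccx * ncell + (cy + oy) % ncell
                j = head[c]
                while j >= 0:
                    if j != i:
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        dx -= box * np.round(dx / box)
                        dy -= box * np.round(dy / box)
                        r2 = dx * dx + dy * dy
                        if r2 < rcut2:
                            if r2 < floor2:
                                return ERR_OVERLAP
                            s2 = sig2 / r2
                            s6 = s2 * s2 * s2
                            f_over_r2 = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                            forces[i, 0] += f_over_r2 * dx
                            forces[i, 1] += f_over_r2 * dy
                    j = nxt[j]
    return OK


@njit(cache=True)
def _lj_forces_brute(pos, forces, box, eps, sigma, rcut):
    """All-pairs minimum-image LJ forces (small systems / tiny boxes)."""
    n = pos.shape[0]
    rcut2 = rcut * rcut
    floor2 = (1e-6 * sigma) ** 2
    sig2 = sigma * sigma
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            r2 = dx * dx + dy * dy
            if r2 < rcut2:
                if r2 < floor2:
                    return ERR_OVERLAP
                s2 = sig2 / r2
                s6 = s2 * s2 * s2
                f_over_r2 = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                forces[i, 0] += f_over_r2 * dx
                forces[i, 1] += f_over_r2 * dy
                forces[j, 0] -= f_over_r2 * dx
                forces[j, 1] -= f_over_r2 * dy
    return OK


@njit(cache=True)
def run_langevin(pos, unw, cbar, grid_dx, box, cb, D0, kBT, dt,
                 eps, sigma, rcut, pref_code, chi,
                 n_steps, first_record, sample_every, seed, out):
    """Overdamped Langevin propagation with field-dependent diffusivity.

    Euler–Maruyama in the Ito convention: the diffusivity is evaluated at
    the pre-move position and no spurious-drift correction is applied.
    ``pref_code``: 0 none, 1 Lo-preference, 2 Ld-preference; ``chi`` is the
    rejection probability (fraction, not percent) applied to moves leaving
    the preferred domain.  Samples of the unwrapped positions are written to
    ``out`` at steps ``first_record + k*sample_every``.  ``pos`` and ``unw``
    are updated in place.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    L = cbar.shape[0]
    inv_dx = 1.0 / grid_dx
    half = 0.5 * box
    use_forces = eps > 0.0
    ncell = int(box // rcut) if use_forces else 1
    brute = ncell < 3
    head = np.full(max(ncell * ncell, 1), -1, np.int64)
    nxt = np.empty(n, np.int64)
    forces = np.zeros((n, 2))
    rec = 0
    n_rec = out.shape[0]
    for s in range(n_steps + 1):
        if s >= first_record and (s - first_record) % sample_every == 0 and rec < n_rec:
            for i in range(n):
                out[rec, i, 0] = unw[i, 0]
                out[rec, i, 1] = unw[i, 1]
            rec += 1
        if s == n_steps:
            break
        if use_forces:
            if brute:
                err = _lj_forces_brute(pos, forces, box, eps, sigma, rcut)
            else:
                err = _lj_forces(pos, forces, box, eps, sigma, rcut, head, nxt, ncell)
            if err != OK:
                return err
        for i in range(n):
            x = pos[i, 0]
            y = pos[i, 1]
            c_here = _bilinear(cbar, x, y, inv_dx, L)
            D = (cb + c_here) * D0
            sd = np.sqrt(2.0 * D * dt)
            ddx = sd * np.random.normal()
            ddy = sd * np.random.normal()
            if use_forces:
                fac = D / kBT * dt
                ddx += fac * forces[i, 0]
                ddy += fac * forces[i, 1]
            if abs(ddx) > half or abs(ddy) > half:
                return ERR_STEP_TOO_LARGE
            nx = x + ddx
            ny = y + ddy
            accept = True
            if pref_code != 0:
                old_lo = c_here < 0.5
                new_lo = _bilinear(cbar, nx, ny, inv_dx, L) < 0.5
                if pref_code == 1:
                    if old_lo and not new_lo and np.random.random() < chi:
                        accept = False
                else:
                    if (not old_lo) and new_lo and np.random.random() < chi:
                        accept = False
            if accept:
                unw[i, 0] += ddx
                unw[i, 1] += ddy
                pos[i, 0] = nx % box
                pos[i, 1] = ny % box
    return OK


@njit(cache=True)
def langevin_block(pos, unw, cbar, grid_dx, box, cb, D0, kBT, dt,
                   eps, sigma, rcut, pref_code, chi, xi, u):
    """A short block of Langevin steps driven by pre-generated noise.

    Identical physics to :func:`run_langevin` but all randomness comes from
    the caller: ``xi`` is ``(n_steps, n, 2)`` standard Gaussians and ``u``
    is ``(n_steps, n)`` uniforms used by the preference filter.  Used by the
    two-way-coupled integrator so one NumPy generator drives the whole run.
    """
    n = pos.shape[0]
    L = cbar.shape[0]
    inv_dx = 1.0 / grid_dx
    half = 0.5 * box
    n_steps = xi.shape[0]
    use_forces = eps > 0.0
    ncell = int(box // rcut) if use_forces else 1
    brute = ncell < 3
    head = np.full(max(ncell * ncell, 1), -1, np.int64)
    nxt = np.empty(n, np.int64)
    forces = np.zeros((n, 2))
    for s in range(n_steps):
        if use_forces:
            if brute:
                err = _lj_forces_brute(pos, forces, box, eps, sigma, rcut)
            else:
                err = _lj_forces(pos, forces, box, eps, sigma, rcut, head, nxt, ncell)
            if err != OK:
                return err
        for i in range(n):
            x = pos[i, 0]
            y = pos[i, 1]
            c_here = _bilinear(cbar, x, y, inv_dx, L)
            D = (cb + c_here) * D0
            sd = np.sqrt(2.0 * D * dt)
            ddx = sd * xi[s, i, 0]
            ddy = sd * xi[s, i, 1]
            if use_forces:
                fac = D / kBT * dt
                ddx += fac * forces[i, 0]
                ddy += fac * forces[i, 1]
            if abs(ddx) > half or abs(ddy) > half:
                return ERR_STEP_TOO_LARGE
            nx = x + ddx
            ny = y + ddy
            accept = True
            if pref_code != 0:
                old_lo = c_here < 0.5
                new_lo = _bilinear(cbar, nx, ny, inv_dx, L) < 0.5
                if pref_code == 1:
                    if old_lo and not new_lo and u[s, i] < chi:
                        accept = False
                else:
                    if (not old_lo) and new_lo and u[s, i] < chi:
                        accept = False
            if accept:
                unw[i, 0] += ddx
                unw[i, 1] += ddy
                pos[i, 0] = nx % box
                pos[i, 1] = ny % box
    return OK


@njit(cache=True)
def fpt_1d(n_walkers, x_target, D, dt, t_max, seed, out):
    """First-passage times of 1-D Brownian walkers from 0 to level ``x``.

    Euler steps with a Brownian-bridge crossing test between steps, which
    removes the O(sqrt(dt)) bias of naive threshold detection: a bridge
    from a to b (both below x) crosses x within one step with probability
    exp(-(x-a)(x-b)/(D*dt)) for increment variance 2*D*dt.  Walkers that
    have not passed by ``t_max`` get ``out = -1``.
    """
    np.random.seed(seed)
    sd = np.sqrt(2.0 * D * dt)
    near = 7.0 * sd  # bridge crossing probability < 1e-21 beyond this
    n_max = int(t_max / dt)
    for w in range(n_walkers):
        p = 0.0
        hit = -1.0
        for s in range(1, n_max + 1):
            q = p + sd * np.random.normal()
            if q >= x_target:
                hit = s * dt
                break
            if x_target - q < near and x_target - p < near:
                pc = np.exp(-(x_target - p) * (x_target - q) / (D * dt))
                if np.random.random() < pc:
                    hit = s * dt
                    break
            p = q
        out[w] = hit
    return OK


@njit(cache=True)
def deposit_source(pos, grid, alpha_g, r_g, sigma, grid_dx, box, r_trunc):
    """Sum the piecewise protein-lipid kernel g(r) over particles onto a grid.

    g = alpha_g for r <= sigma, alpha_g*exp(-(r-sigma)/r_g) beyond, truncated
    at ``r_trunc``.  The window per particle must fit in the box (checked by
    the caller); node distances are then automatically minimum-image.
    """
    L = grid.shape[0]
    for i in range(L):
        for j in range(L):
            grid[i, j] = 0.0
    w = int(np.ceil(r_trunc / grid_dx))
    for p in range(pos.shape[0]):
        px = pos[p, 0]
        py = pos[p, 1]
        i0 = int(np.floor(px / grid_dx))
        j0 = int(np.floor(py / grid_dx))
        for di in range(-w, w + 1):
            rx = (i0 + di) * grid_dx - px
            ii = (i0 + di) % L
            for dj in range(-w, w + 1):
                ry = (j0 + dj) * grid_dx - py
                r = np.sqrt(rx * rx + ry * ry)
                if r <= sigma:
                    grid[ii, (j0 + dj) % L] += alpha_g
                elif r <= r_trunc:
                    grid[ii, (j0 + dj) % L] += alpha_g * np.exp(-(r - sigma) / r_g)
    return OK


@njit(cache=True)
def euler_ch_step(c, k, uniform_k, W2, Lambda, M, inv_tau, c_r, dt, inv_dx2,
                  eta, use_eta, mu, c_out):
    """One explicit-Euler Cahn-Hilliard step on a periodic grid.

    Same discrete operators as the NumPy reference in ldpf.phasefield
    (5-point Laplacian; flux-form divergence when the gradient coefficient
    ``k`` varies, signalled by ``uniform_k = False``).  ``eta`` is the
    pre-generated noise grid for this step.  Returns max |c_new| so the
    caller can detect blow-up.
    """
    L = c.shape[0]
    for i in range(L):
        im = (i - 1) % L
        ip = (i + 1) % L
        for j in range(L):
            jm = (j - 1) % L
            jp = (j + 1) % L
            cc = c[i, j]
            if uniform_k:
                grad = -W2 * (c[ip, j] + c[im, j] + c[i, jp] + c[i, jm]
                              - 4.0 * cc) * inv_dx2
            else:
                kc = k[i, j]
                kxp = 0.5 * (kc + k[ip, j])
                kxm = 0.5 * (kc + k[im, j])
                kyp = 0.5 * (kc + k[i, jp])
                kym = 0.5 * (kc + k[i, jm])
                grad = -(kxp * (c[ip, j] - cc) - kxm * (cc - c[im, j])
                         + kyp * (c[i, jp] - cc) - kym * (cc - c[i, jm])) * inv_dx2
            mu[i, j] = grad + Lambda * cc + cc * cc * cc
    peak = 0.0
    for i in range(L):
        im = (i - 1) % L
        ip = (i + 1) % L
        for j in range(L):
            jm = (j - 1) % L
            jp = (j + 1) % L
            lap_mu = (mu[ip, j] + mu[im, j] + mu[i, jp] + mu[i, jm]
                      - 4.0 * mu[i, j]) * inv_dx2
            v = c[i, j] + dt * (M * lap_mu - inv_tau * (c[i, j] - c_r))
            if use_eta:
                v += eta[i, j]
            c_out[i, j] = v
            a = abs(v)
            if a > peak:
                peak = a
    return peak
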