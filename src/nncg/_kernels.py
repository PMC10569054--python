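"""Numba kernels for the Metropolis samplers.

All energies are in k_B*T units (beta = 1).  Three energy models are
supported: truncated Lennard-Jones, a tabulated pair potential with
floor-bin lookup, and the bias-free feed-forward network over Gaussian G2
descriptors.  The network sampler keeps the N x K descriptor matrix and
per-site energies incrementally up to date (a single-site move only
touches the moved row plus the rows of sites within r_c of the old or new
position) and periodically rebuilds both from scratch to cap float drift.

Weight layout matches nncg.network: per layer a row-major (out, in)
matrix, concatenated flat.  RNG: numpy's legacy generator seeded inside
the jitted function, so runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# model kind tags for the pair sampler
KIND_LJ = 0
KIND_TABLE = 1


@njit(cache=False)
def _dist2_to(pos, box, i, p, d2):
    """Minimum-image squared distances from point p to every site (self=inf)."""
    n = pos.shape[0]
    for k in range(n):
        dx = pos[k, 0] - p[0]
        dy = pos[k, 1] - p[1]
        dz = pos[k, 2] - p[2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        d2[k] = dx * dx + dy * dy + dz * dz
    d2[i] = 1e300


@njit(cache=False)
def _pair_energy(d2, i, kind, eps4, sig2, rc2, table, dr_t):
    """Sum of pair energies between site i (at the point used for d2) and all."""
    e = 0.0
    nb = table.shape[0]
    rmax2_t = (nb * dr_t) ** 2
    n = d2.shape[0]
    for k in range(n):
        if k == i:
            continue
        r2 = d2[k]
        if kind == KIND_LJ:
            if r2 < rc2:
                s6 = (sig2 / r2) ** 3
                e += eps4 * (s6 * s6 - s6)
        else:
            if r2 < rmax2_t:
                b = int(np.sqrt(r2) / dr_t)
                if b < nb:
                    e += table[b]
    return e


@njit(cache=False)
def _full_pair_energy(pos, box, kind, eps4, sig2, rc2, table, dr_t):
    n = pos.shape[0]
    d2 = np.empty(n)
    e = 0.0
    for i in range(n):
        _dist2_to(pos, box, i, pos[i], d2)
        e += _pair_energy(d2, i, kind, eps4, sig2, rc2, table, dr_t)
    return 0.5 * e


@njit(cache=False)
def _hist_pairs(pos, box, dr, nb, out):
    """Accumulate the unordered minimum-image pair-distance histogram."""
    n = pos.shape[0]
    rmax2 = (nb * dr) ** 2
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= box[0] * np.round(dx / box[0])
            dy -= box[1] * np.round(dy / box[1])
            dz -= box[2] * np.round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rmax2:
                b = int(np.sqrt(r2) / dr)
                if b < nb:
                    out[b] += 1.0


@njit(cache=False)
def _forward(g, w, sizes, a, b):
    """Site energy for one descriptor row; a, b are scratch >= max width."""
    nin = sizes[0]
    for i in range(nin):
        a[i] = g[i]
    off = 0
    n_layers = sizes.shape[0] - 1
    for l in range(n_layers):
        nin = sizes[l]
        nout = sizes[l + 1]
        for j in range(nout):
            s = 0.0
            base = off + j * nin
            for i in range(nin):
                s += w[base + i] * a[i]
            if l < n_layers - 1 and s < 0.0:
                s = 0.0  # ReLU on hidden layers
            b[j] = s
        for j in range(nout):
            a[j] = b[j]
        off += nin * nout
    return a[0]


@njit(cache=False)
def _site_energy_grad(g, w, sizes, grad, acts, delta, delta_prev):
    """Forward + reverse pass for one site; dE/dw accumulated into grad.

    acts: scratch of length sum(sizes); delta/delta_prev: length max width.
    Returns the site energy.  ReLU'(0) := 0.
    """
    n_layers = sizes.shape[0] - 1
    for i in range(sizes[0]):
        acts[i] = g[i]
    off_w = 0
    pos = 0
    for l in range(n_layers):
        nin = sizes[l]
        nout = sizes[l + 1]
        for j in range(nout):
            s = 0.0
            base = off_w + j * nin
            for i in range(nin):
                s += w[base + i] * acts[pos + i]
            if l < n_layers - 1 and s < 0.0:
                s = 0.0
            acts[pos + nin + j] = s
        pos += nin
        off_w += nin * nout
    energy = acts[pos]
    delta[0] = 1.0
    for l in range(n_layers - 1, -1, -1):
        nin = sizes[l]
        nout = sizes[l + 1]
        off_w -= nin * nout
        pos -= nin
        for j in range(nout):
            dj = delta[j]
            base = off_w + j * nin
            for i in range(nin):
                grad[base + i] += dj * acts[pos + i]
        if l > 0:
            for i in range(nin):
                s = 0.0
                for j in range(nout):
                    s += delta[j] * w[off_w + j * nin + i]
                if acts[pos + i] <= 0.0:
                    s = 0.0
                delta_prev[i] = s
            for i in range(nin):
                delta[i] = delta_prev[i]
    return energy


@njit(cache=False)
def _g2_add_pair(row, r, eta, rs, rc, sign):
    """Add (sign=+1) or remove (sign=-1) one pair's G2 contribution."""
    if r >= rc:
        return
    f = 0.5 * (np.cos(np.pi * r / rc) + 1.0)
    for q in range(eta.shape[0]):
        d = r - rs[q]
        row[q] += sign * np.exp(-eta[q] * d * d) * f


@njit(cache=False)
def _build_g2(pos, box, eta, rs, rc, G):
    n = pos.shape[0]
    K = eta.shape[0]
    for i in range(n):
        for q in range(K):
            G[i, q] = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= box[0] * np.round(dx / box[0])
            dy -= box[1] * np.round(dy / box[1])
            dz -= box[2] * np.round(dz / box[2])
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < rc:
                _g2_add_pair(G[i], r, eta, rs, rc, 1.0)
                _g2_add_pair(G[j], r, eta, rs, rc, 1.0)


@njit(cache=False)
def mc_pair(
    pos0,
    box,
    kind,
    eps4,
    sig2,
    rc2,
    table,
    dr_t,
    n_steps,
    n_equil,
    out_freq,
    adapt_interval,
    target_acc,
    max_disp0,
    rdf_dr,
    rdf_nb,
    collect_cov,
    n_frames,
    seed,
):
    """Metropolis MC under a pair potential (LJ or tabulated).

    Returns (final positions, histogram sum, S-covariance sums, sample
    count, production acceptance ratio, final max_disp, frames, n_saved).
    """
    np.random.seed(seed)
    pos = pos0.copy()
    n = pos.shape[0]
    d2o = np.empty(n)
    d2n = np.empty(n)
    newp = np.empty(3)
    max_disp = max_disp0
    disp_cap = min(box[0], min(box[1], box[2])) / 4.0
    acc_win = 0
    tries_win = 0
    acc_prod = 0
    n_prod = 0
    hist_sum = np.zeros(rdf_nb)
    S = np.zeros(rdf_nb)
    nb_cov = rdf_nb if collect_cov else 1
    sum_SS = np.zeros((nb_cov, nb_cov))
    n_samples = 0
    nf = max(n_frames, 1)
    frames = np.zeros((nf, n, 3))
    n_prod_steps = n_steps - n_equil
    frame_interval = n_prod_steps // n_frames if n_frames > 0 else n_prod_steps + 1
    fidx = 0
    for step in range(n_steps):
        i = np.random.randint(0, n)
        for c in range(3):
            x = pos[i, c] + (2.0 * np.random.random() - 1.0) * max_disp
            x -= box[c] * np.floor(x / box[c])
            newp[c] = x
        _dist2_to(pos, box, i, pos[i], d2o)
        _dist2_to(pos, box, i, newp, d2n)
        e_old = _pair_energy(d2o, i, kind, eps4, sig2, rc2, table, dr_t)
        e_new = _pair_energy(d2n, i, kind, eps4, sig2, rc2, table, dr_t)
        dE = e_new - e_old
        accepted = False
        if np.isfinite(dE):
            if dE <= 0.0:
                accepted = True
            elif np.random.random() < np.exp(-dE):
                accepted = True
        if accepted:
            pos[i, 0] = newp[0]
            pos[i, 1] = newp[1]
            pos[i, 2] = newp[2]
        tries_win += 1
        if accepted:
            acc_win += 1
        in_prod = step >= n_equil
        if in_prod:
            n_prod += 1
            if accepted:
                acc_prod += 1
        if tries_win == adapt_interval:
            if not in_prod:
                rate = acc_win / adapt_interval
                max_disp *= 1.0 + 0.5 * (rate - target_acc)
                if max_disp < 1e-3:
                    max_disp = 1e-3
                if max_disp > disp_cap:
                    max_disp = disp_cap
            acc_win = 0
            tries_win = 0
        if in_prod:
            k = step - n_equil + 1
            if k % out_freq == 0:
                for b in range(rdf_nb):
                    S[b] = 0.0
                _hist_pairs(pos, box, rdf_dr, rdf_nb, S)
                for b in range(rdf_nb):
                    hist_sum[b] += S[b]
                if collect_cov:
                    for b in range(rdf_nb):
                        sb = S[b]
                        if sb != 0.0:
                            for g in range(rdf_nb):
                                sum_SS[b, g] += sb * S[g]
                n_samples += 1
            if n_frames > 0 and k % frame_interval == 0 and fidx < n_frames:
                for a in range(n):
                    frames[fidx, a, 0] = pos[a, 0]
                    frames[fidx, a, 1] = pos[a, 1]
                    frames[fidx, a, 2] = pos[a, 2]
                fidx += 1
    acc_ratio = acc_prod / max(n_prod, 1)
    return pos, hist_sum, sum_SS, n_samples, acc_ratio, max_disp, frames, fidx


@njit(cache=False)
def mc_network(
    pos0,
    box,
    eta,
    rs,
    rc,
    w,
    sizes,
    n_steps,
    n_equil,
    out_freq,
    adapt_interval,
    target_acc,
    max_disp0,
    rdf_dr,
    rdf_nb,
    collect_grad,
    refresh_interval,
    n_frames,
    seed,
):
    """Metropolis MC under the G2 neural-network energy.

    Returns (final positions, histogram sum, sum of dE/dw samples, sum of
    S x dE/dw cross products, sample count, production acceptance ratio,
    final max_disp, frames, n_saved, final tracked total energy).
    """
    np.random.seed(seed)
    pos = pos0.copy()
    n = pos.shape[0]
    K = eta.shape[0]
    nw = w.shape[0]
    rc2 = rc * rc
    G = np.zeros((n, K))
    En = np.zeros(n)
    maxw = 0
    tot_w = 0
    for l in range(sizes.shape[0]):
        if sizes[l] > maxw:
            maxw = sizes[l]
        tot_w += sizes[l]
    buf_a = np.empty(maxw)
    buf_b = np.empty(maxw)
    acts = np.empty(tot_w)
    dbuf = np.empty(maxw)
    dbuf2 = np.empty(maxw)
    # transposed per-layer weight matrices for batched candidate forwards
    n_layers = sizes.shape[0] - 1
    wts = []
    off_w = 0
    for l in range(n_layers):
        nin = sizes[l]
        nout = sizes[l + 1]
        wt = np.empty((nin, nout))
        for j in range(nout):
            for i in range(nin):
                wt[i, j] = w[off_w + j * nin + i]
        wts.append(wt)
        off_w += nin * nout

    _build_g2(pos, box, eta, rs, rc, G)
    for a in range(n):
        En[a] = _forward(G[a], w, sizes, buf_a, buf_b)

    d2o = np.empty(n)
    d2n = np.empty(n)
    newp = np.empty(3)
    cand_rows = np.empty((n, K))
    cand_E = np.empty(n)
    cand_idx = np.empty(n, dtype=np.int64)

    max_disp = max_disp0
    disp_cap = min(box[0], min(box[1], box[2])) / 4.0
    acc_win = 0
    tries_win = 0
    acc_prod = 0
    n_prod = 0
    hist_sum = np.zeros(rdf_nb)
    S = np.zeros(rdf_nb)
    ng = nw if collect_grad else 1
    sum_dEdw = np.zeros(ng)
    sum_cross = np.zeros((rdf_nb if collect_grad else 1, ng))
    grad_s = np.zeros(ng)
    n_samples = 0
    nf = max(n_frames, 1)
    frames = np.zeros((nf, n, 3))
    n_prod_steps = n_steps - n_equil
    frame_interval = n_prod_steps // n_frames if n_frames > 0 else n_prod_steps + 1
    fidx = 0

    for step in range(n_steps):
        i = np.random.randint(0, n)
        for c in range(3):
            x = pos[i, c] + (2.0 * np.random.random() - 1.0) * max_disp
            x -= box[c] * np.floor(x / box[c])
            newp[c] = x
        _dist2_to(pos, box, i, pos[i], d2o)
        _dist2_to(pos, box, i, newp, d2n)
        # candidate row 0 is the moved site's fresh descriptor row
        for q in range(K):
            cand_rows[0, q] = 0.0
        ncand = 1
        for k in range(n):
            if k == i:
                continue
            r2n = d2n[k]
            r2o = d2o[k]
            inside_new = r2n < rc2
            inside_old = r2o < rc2
            if inside_new:
                _g2_add_pair(cand_rows[0], np.sqrt(r2n), eta, rs, rc, 1.0)
            if inside_new or inside_old:
                for q in range(K):
                    cand_rows[ncand, q] = G[k, q]
                if inside_old:
                    _g2_add_pair(cand_rows[ncand], np.sqrt(r2o), eta, rs, rc, -1.0)
                if inside_new:
                    _g2_add_pair(cand_rows[ncand], np.sqrt(r2n), eta, rs, rc, 1.0)
                cand_idx[ncand] = k
                ncand += 1
        # batched forward over all candidate rows (BLAS matmul per layer)
        act = np.dot(cand_rows[:ncand], wts[0])
        for l in range(1, n_layers):
            for ci in range(ncand):
                for j in range(act.shape[1]):
                    if act[ci, j] < 0.0:
                        act[ci, j] = 0.0
            act = np.dot(act, wts[l])
        for ci in range(ncand):
            cand_E[ci] = act[ci, 0]
        e_i_new = cand_E[0]
        dE = e_i_new - En[i]
        for c in range(1, ncand):
            dE += cand_E[c] - En[cand_idx[c]]
        accepted = False
        if np.isfinite(dE):
            if dE <= 0.0:
                accepted = True
            elif np.random.random() < np.exp(-dE):
                accepted = True
        if accepted:
            pos[i, 0] = newp[0]
            pos[i, 1] = newp[1]
            pos[i, 2] = newp[2]
            for q in range(K):
                G[i, q] = cand_rows[0, q]
            En[i] = e_i_new
            for c in range(1, ncand):
                k = cand_idx[c]
                for q in range(K):
                    G[k, q] = cand_rows[c, q]
                En[k] = cand_E[c]
        tries_win += 1
        if accepted:
            acc_win += 1
        in_prod = step >= n_equil
        if in_prod:
            n_prod += 1
            if accepted:
                acc_prod += 1
        if tries_win == adapt_interval:
            if not in_prod:
                rate = acc_win / adapt_interval
                max_disp *= 1.0 + 0.5 * (rate - target_acc)
                if max_disp < 1e-3:
                    max_disp = 1e-3
                if max_disp > disp_cap:
                    max_disp = disp_cap
            acc_win = 0
            tries_win = 0
        if refresh_interval > 0 and (step + 1) % refresh_interval == 0:
            _build_g2(pos, box, eta, rs, rc, G)
            for a in range(n):
                En[a] = _forward(G[a], w, sizes, buf_a, buf_b)
        if in_prod:
            kk = step - n_equil + 1
            if kk % out_freq == 0:
                for b in range(rdf_nb):
                    S[b] = 0.0
                _hist_pairs(pos, box, rdf_dr, rdf_nb, S)
                for b in range(rdf_nb):
                    hist_sum[b] += S[b]
                if collect_grad:
                    for q in range(nw):
                        grad_s[q] = 0.0
                    for a in range(n):
                        _site_energy_grad(G[a], w, sizes, grad_s, acts, dbuf, dbuf2)
                    for q in range(nw):
                        sum_dEdw[q] += grad_s[q]
                    for b in range(rdf_nb):
                        sb = S[b]
                        if sb != 0.0:
                            for q in range(nw):
                                sum_cross[b, q] += sb * grad_s[q]
                n_samples += 1
            if n_frames > 0 and kk % frame_interval == 0 and fidx < n_frames:
                for a in range(n):
                    frames[fidx, a, 0] = pos[a, 0]
                    frames[fidx, a, 1] = pos[a, 1]
                    frames[fidx, a, 2] = pos[a, 2]
                fidx += 1
    final_E = 0.0
    for a in range(n):
        final_E += En[a]
    acc_ratio = acc_prod / max(n_prod, 1)
    return (
        pos,
        hist_sum,
        sum_dEdw,
        sum_cross,
        n_samples,
        acc_ratio,
        max_disp,
        frames,
        fidx,
        final_E,
    )


@njit(cache=False)
def forward_energy(g, w, sizes):
    """Single-row network forward pass (exposed for cross-checks)."""
    maxw = 0
    for l in range(sizes.shape[0]):
        if sizes[l] > maxw:
            maxw = sizes[l]
    a = np.empty(maxw)
    b = np.empty(maxw)
    return _forward(g, w, sizes, a, b)
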