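"""Numba kernels for the strict-clock MCMC engine.

Felsenstein pruning under Jukes–Cantor exploits the rank-one structure of the
JC transition matrix: the partial flowing up a branch of duration t is
``e * L + (1-e)/4 * sum(L)`` with ``e = exp(-4*r*t/3)``.  Partials are kept
per internal node with a per-site log scaling factor (rescaled only when a
site's maximum drops below a threshold), so a node-age move refreshes just
the ancestor path of the moved node.  Each node owns two partial rows —
current and proposal — flipped on acceptance, which makes reject/restore
free of copying.

Moves (Metropolis–Hastings, fixed topology, fixed clock rate):
  0. uniform age slide of a non-root internal node within (oldest child, parent)
  1. random-walk slide of the root age (rejected below the oldest root child)
  2. multiplicative rescaling of all internal node ages (log-uniform step;
     Hastings factor s**m for m scaled ages)
  3. multiplicative random walk on the birth rate (Hastings factor s)

The tree prior is the Yule density on the fixed labelled topology,
``(n-2) log(lam) - lam * L`` with L the total branch length including both
root branches; conditional on the root age this makes the non-root node ages
i.i.d. truncated exponentials, matching the conditioned tree simulator.
"""

import numpy as np
from numba import njit

RESCALE_THRESHOLD = 1e-200


@njit(cache=True, fastmath=True, inline="always")
def _store_site(partials, logscale, target, s, p0, p1, p2, p3, lsv):
    mx = p0
    if p1 > mx:
        mx = p1
    if p2 > mx:
        mx = p2
    if p3 > mx:
        mx = p3
    if mx < RESCALE_THRESHOLD and mx > 0.0:
        inv = 1.0 / mx
        p0 *= inv
        p1 *= inv
        p2 *= inv
        p3 *= inv
        lsv += np.log(mx)
    partials[target, s, 0] = p0
    partials[target, s, 1] = p1
    partials[target, s, 2] = p2
    partials[target, s, 3] = p3
    logscale[target, s] = lsv


@njit(cache=True, fastmath=True)
def _node_tip_tip(t0, t1, e0, a0, e1, a1, tip_state, partials, logscale, target):
    nsites = tip_state.shape[1]
    for s in range(nsites):
        b0 = tip_state[t0, s]
        b1 = tip_state[t1, s]
        w = a0 * a1
        p0 = w
        p1 = w
        p2 = w
        p3 = w
        if b0 == b1:
            # same observed base: that state gets (a0+e0)(a1+e1)
            pb = (a0 + e0) * (a1 + e1)
            if b0 == 0:
                p0 = pb
            elif b0 == 1:
                p1 = pb
            elif b0 == 2:
                p2 = pb
            else:
                p3 = pb
        else:
            x0 = (a0 + e0) * a1
            x1 = a0 * (a1 + e1)
            if b0 == 0:
                p0 = x0
            elif b0 == 1:
                p1 = x0
            elif b0 == 2:
                p2 = x0
            else:
                p3 = x0
            if b1 == 0:
                p0 = x1
            elif b1 == 1:
                p1 = x1
            elif b1 == 2:
                p2 = x1
            else:
                p3 = x1
        _store_site(partials, logscale, target, s, p0, p1, p2, p3, 0.0)


@njit(cache=True, fastmath=True)
def _node_tip_int(t0, row1, e0, a0, e1, a1, tip_state, partials, logscale, target):
    nsites = tip_state.shape[1]
    for s in range(nsites):
        l0 = partials[row1, s, 0]
        l1 = partials[row1, s, 1]
        l2 = partials[row1, s, 2]
        l3 = partials[row1, s, 3]
        t = a1 * (l0 + l1 + l2 + l3)
        u0 = t + e1 * l0
        u1 = t + e1 * l1
        u2 = t + e1 * l2
        u3 = t + e1 * l3
        b0 = tip_state[t0, s]
        p0 = a0 * u0
        p1 = a0 * u1
        p2 = a0 * u2
        p3 = a0 * u3
        if b0 == 0:
            p0 += e0 * u0
        elif b0 == 1:
            p1 += e0 * u1
        elif b0 == 2:
            p2 += e0 * u2
        else:
            p3 += e0 * u3
        _store_site(partials, logscale, target, s, p0, p1, p2, p3, logscale[row1, s])


@njit(cache=True, fastmath=True)
def _node_int_int(row0, row1, e0, a0, e1, a1, partials, logscale, target):
    nsites = partials.shape[1]
    for s in range(nsites):
        l0 = partials[row0, s, 0]
        l1 = partials[row0, s, 1]
        l2 = partials[row0, s, 2]
        l3 = partials[row0, s, 3]
        t = a0 * (l0 + l1 + l2 + l3)
        w0 = t + e0 * l0
        w1 = t + e0 * l1
        w2 = t + e0 * l2
        w3 = t + e0 * l3
        m0 = partials[row1, s, 0]
        m1 = partials[row1, s, 1]
        m2 = partials[row1, s, 2]
        m3 = partials[row1, s, 3]
        t = a1 * (m0 + m1 + m2 + m3)
        _store_site(
            partials,
            logscale,
            target,
            s,
            w0 * (t + e1 * m0),
            w1 * (t + e1 * m1),
            w2 * (t + e1 * m2),
            w3 * (t + e1 * m3),
            logscale[row0, s] + logscale[row1, s],
        )


@njit(cache=True, fastmath=True)
def _update_node(v, children, ages, tip_state, partials, logscale, cur, pend, rate, n_tips):
    """Recompute node v's partials into its proposal row and mark it pending.

    Children marked pending are read from their proposal rows.
    """
    vi = v - n_tips
    c0 = children[v, 0]
    c1 = children[v, 1]
    e0 = np.exp(-4.0 * rate * (ages[v] - ages[c0]) / 3.0)
    e1 = np.exp(-4.0 * rate * (ages[v] - ages[c1]) / 3.0)
    a0 = 0.25 * (1.0 - e0)
    a1 = 0.25 * (1.0 - e1)
    target = 2 * vi + (1 - cur[vi])
    if c0 < n_tips and c1 < n_tips:
        _node_tip_tip(c0, c1, e0, a0, e1, a1, tip_state, partials, logscale, target)
    elif c0 < n_tips:
        i1 = c1 - n_tips
        row1 = 2 * i1 + (cur[i1] ^ pend[i1])
        _node_tip_int(c0, row1, e0, a0, e1, a1, tip_state, partials, logscale, target)
    elif c1 < n_tips:
        i0 = c0 - n_tips
        row0 = 2 * i0 + (cur[i0] ^ pend[i0])
        _node_tip_int(c1, row0, e1, a1, e0, a0, tip_state, partials, logscale, target)
    else:
        i0 = c0 - n_tips
        i1 = c1 - n_tips
        row0 = 2 * i0 + (cur[i0] ^ pend[i0])
        row1 = 2 * i1 + (cur[i1] ^ pend[i1])
        _node_int_int(row0, row1, e0, a0, e1, a1, partials, logscale, target)
    pend[vi] = 1


@njit(cache=True, fastmath=True)
def _root_loglik(root, partials, logscale, cur, pend, n_tips):
    ri = root - n_tips
    row = 2 * ri + (cur[ri] ^ pend[ri])
    nsites = partials.shape[1]
    total = 0.0
    for s in range(nsites):
        sitesum = (
            partials[row, s, 0]
            + partials[row, s, 1]
            + partials[row, s, 2]
            + partials[row, s, 3]
        )
        if sitesum <= 0.0:
            return -1e300
        total += np.log(0.25 * sitesum) + logscale[row, s]
    return total


@njit(cache=True, fastmath=True)
def _commit(pend, cur, accept):
    n = pend.shape[0]
    for i in range(n):
        if pend[i]:
            if accept:
                cur[i] = 1 - cur[i]
            pend[i] = 0


@njit(cache=True, fastmath=True)
def _propose_path(
    v, parent, children, ages, tip_state, partials, logscale, cur, pend, rate, n_tips, root):
    """Recompute v and its ancestors into proposal rows; return new loglik."""
    u = v
    while u != -1:
        _update_node(
            u, children, ages, tip_state, partials, logscale, cur, pend, rate, n_tips
        )
        u = parent[u]
    return _root_loglik(root, partials, logscale, cur, pend, n_tips)


@njit(cache=True, fastmath=True)
def _propose_full(
    postorder, children, ages, tip_state, partials, logscale, cur, pend, rate, n_tips, root):
    for k in range(postorder.shape[0]):
        _update_node(
            postorder[k], children, ages, tip_state, partials, logscale, cur, pend, rate,
            n_tips,
        )
    return _root_loglik(root, partials, logscale, cur, pend, n_tips)


@njit(cache=True)
def run_chain(
    parent,
    children,
    ages_init,
    postorder,
    tip_state,
    rate,
    lam_init,
    lam_max,
    use_lik,
    sample_lam,
    sample_root,
    n_steps,
    thin,
    p_slide,
    p_rootslide,
    p_scale,
    root_window,
    scale_step,
    rate_step,
    seed,
):
    """Metropolis–Hastings over internal node ages and the birth rate.

    Returns thinned samples: root height, birth rate, log prior, log
    likelihood, all internal node ages, plus per-move (accept, propose)
    counts for moves (slide, root slide, tree scale, rate).
    """
    np.random.seed(seed)
    n_tips = tip_state.shape[0]
    n_int = n_tips - 1
    ages = ages_init.copy()
    root = -1
    for v in range(parent.shape[0]):
        if parent[v] == -1:
            root = v

    nsites = tip_state.shape[1]
    partials = np.zeros((2 * n_int, nsites, 4))
    logscale = np.zeros((2 * n_int, nsites))
    cur = np.zeros(n_int, dtype=np.int8)
    pend = np.zeros(n_int, dtype=np.int8)
    if use_lik:
        loglik = _propose_full(
            postorder, children, ages, tip_state, partials, logscale, cur, pend, rate,
            n_tips, root,
        )
        _commit(pend, cur, True)
    else:
        loglik = 0.0

    # total branch length: both root branches count the root age
    L = 2.0 * ages[root]
    for v in range(n_tips, parent.shape[0]):
        if v != root:
            L += ages[v]
    lam = lam_init
    logprior = (n_tips - 2) * np.log(lam) - lam * L

    n_out = n_steps // thin
    out_root = np.empty(n_out)
    out_lam = np.empty(n_out)
    out_lp = np.empty(n_out)
    out_ll = np.empty(n_out)
    out_ages = np.empty((n_out, n_int))
    accepts = np.zeros(4, dtype=np.int64)
    proposals = np.zeros(4, dtype=np.int64)

    out_i = 0
    for step in range(n_steps):
        u01 = np.random.random()
        if u01 < p_slide:
            move = 0
        elif u01 < p_slide + p_rootslide:
            move = 1 if sample_root else 0
        elif u01 < p_slide + p_rootslide + p_scale:
            move = 2 if sample_root else 0
        else:
            move = 3 if sample_lam else 0
        if n_int == 1 and move == 0:
            # a two-tip tree has no non-root internal node to slide
            move = 1 if sample_root else 3
        proposals[move] += 1

        if move == 0:
            # uniform slide of a non-root internal node within its bracket
            v = n_tips + np.random.randint(n_int)
            while v == root:
                v = n_tips + np.random.randint(n_int)
            lo = ages[children[v, 0]]
            alt = ages[children[v, 1]]
            if alt > lo:
                lo = alt
            hi = ages[parent[v]]
            x_old = ages[v]
            x_new = lo + np.random.random() * (hi - lo)
            d_prior = -lam * (x_new - x_old)
            ages[v] = x_new
            if use_lik:
                new_ll = _propose_path(
                    v, parent, children, ages, tip_state, partials, logscale, cur, pend,
                    rate, n_tips, root,
                )
            else:
                new_ll = 0.0
            if np.log(np.random.random()) < d_prior + (new_ll - loglik):
                accepts[0] += 1
                loglik = new_ll
                logprior += d_prior
                L += x_new - x_old
                _commit(pend, cur, True)
            else:
                ages[v] = x_old
                _commit(pend, cur, False)
        elif move == 1:
            # random-walk slide of the root age
            lo = ages[children[root, 0]]
            alt = ages[children[root, 1]]
            if alt > lo:
                lo = alt
            x_old = ages[root]
            x_new = x_old + (np.random.random() * 2.0 - 1.0) * root_window
            if x_new > lo:
                d_prior = -2.0 * lam * (x_new - x_old)
                ages[root] = x_new
                if use_lik:
                    _update_node(
                        root, children, ages, tip_state, partials, logscale, cur, pend,
                        rate, n_tips,
                    )
                    new_ll = _root_loglik(root, partials, logscale, cur, pend, n_tips)
                else:
                    new_ll = 0.0
                if np.log(np.random.random()) < d_prior + (new_ll - loglik):
                    accepts[1] += 1
                    loglik = new_ll
                    logprior += d_prior
                    L += 2.0 * (x_new - x_old)
                    _commit(pend, cur, True)
                else:
                    ages[root] = x_old
                    _commit(pend, cur, False)
        elif move == 2:
            # rescale all internal node ages; Hastings factor s**m
            s = np.exp((np.random.random() * 2.0 - 1.0) * scale_step)
            for v in range(n_tips, parent.shape[0]):
                ages[v] *= s
            new_L = s * L
            new_lp = (n_tips - 2) * np.log(lam) - lam * new_L
            if use_lik:
                new_ll = _propose_full(
                    postorder, children, ages, tip_state, partials, logscale, cur, pend,
                    rate, n_tips, root,
                )
            else:
                new_ll = 0.0
            log_acc = (new_lp - logprior) + (new_ll - loglik) + n_int * np.log(s)
            if np.log(np.random.random()) < log_acc:
                accepts[2] += 1
                loglik = new_ll
                logprior = new_lp
                L = new_L
                _commit(pend, cur, True)
            else:
                inv = 1.0 / s
                for v in range(n_tips, parent.shape[0]):
                    ages[v] *= inv
                _commit(pend, cur, False)
        else:
            # multiplicative random walk on the birth rate; Hastings factor s
            s = np.exp((np.random.random() * 2.0 - 1.0) * rate_step)
            lam_new = lam * s
            if lam_new < lam_max:
                new_lp = (n_tips - 2) * np.log(lam_new) - lam_new * L
                if np.log(np.random.random()) < (new_lp - logprior) + np.log(s):
                    accepts[3] += 1
                    lam = lam_new
                    logprior = new_lp

        if (step + 1) % thin == 0:
            out_root[out_i] = ages[root]
            out_lam[out_i] = lam
            out_lp[out_i] = logprior
            out_ll[out_i] = loglik
            for v in range(n_int):
                out_ages[out_i, v] = ages[n_tips + v]
            out_i += 1

    return out_root, out_lam, out_lp, out_ll, out_ages, accepts, proposals
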