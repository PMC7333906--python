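"""Birth–death and Yule tree simulation.

Two simulators live here.  ``simulate_bd_trajectory`` runs an exact
(Gillespie) birth–death species-count process — the "gambler's ruin" view of
clade survival, in which most small clades are absorbed at zero and a lucky
few escape to exponential growth.  ``simulate_yule_conditioned`` draws
ultrametric crown (or stem) trees from a pure-birth process conditioned on
*both* a fixed age and a fixed number of extant tips — the generating process
used throughout the dating experiments.

Under a Yule process of age ``T`` and rate ``lam`` conditioned on its tip
count, the non-root branching ages ``x`` (Myr before present) are i.i.d.
truncated exponentials with density ``lam * exp(-lam*x) / (1 - exp(-lam*T))``
on (0, T); for a crown clade the root sits exactly at ``T`` and the tip count
of one root child is uniform on ``{1, .., N-1}``.  Topology follows from
splitting a uniformly chosen extant lineage at each branching, which yields
the Yule topology distribution.  These standard conditioned-process results
are re-verified in the test suite against a plain forward-simulation
rejection sampler, which is the behavioural contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import NO_NODE, UltrametricTree

__all__ = [
    "BDParams",
    "YuleCladeSpec",
    "Trajectory",
    "simulate_bd_trajectory",
    "simulate_yule_conditioned",
    "simulate_yule_forward",
    "sample_branching_ages",
    "expected_clade_size",
    "rate_for_expected_size",
]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class BDParams:
    """Birth–death rates, per lineage per Myr.  ``mu = 0`` is the Yule case."""

    lambda_: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("speciation rate lambda_ must be positive")
        if self.mu < 0:
            raise ValueError("extinction rate mu must be non-negative")


@dataclass(frozen=True)
class YuleCladeSpec:
    """A Yule clade conditioned on age and size.

    ``n_founders`` is 2 for a crown clade (root at ``age``) and 1 for a
    stem/total-group clade (origin at ``age``, root at the first branching).
    """

    n_tips: int
    age: float
    birth_rate: float
    n_founders: int = 2

    def __post_init__(self) -> None:
        if self.n_founders not in (1, 2):
            raise ValueError("n_founders must be 1 or 2")
        if self.n_tips < self.n_founders:
            raise ValueError("n_tips must be at least n_founders")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")


@dataclass
class Trajectory:
    """Species-count path of one birth–death realization.

    ``times`` (Myr from the start) and ``counts`` after each event, beginning
    at (0, n0).  ``outcome`` is ``"extinct"`` if the count hit zero before
    ``t_max``, else ``"surviving"``.
    """

    times: np.ndarray
    counts: np.ndarray
    outcome: str

    def to_tsv(self, path: str) -> None:
        arr = np.column_stack([self.times, self.counts])
        np.savetxt(path, arr, delimiter="\t", header="time\tcount", comments="")


def simulate_bd_trajectory(
    params: BDParams,
    n0: int,
    t_max: float,
    seed: int | np.random.Generator | None = None,
    n_cap: int | None = None,
) -> Trajectory:
    """Exact event-driven simulation of the species count of a clade.

    Waiting times are exponential with total rate ``n * (lambda + mu)``;
    each event is a speciation with probability ``lambda / (lambda + mu)``.
    Zero is absorbing (clade extinction).  ``n_cap``, if given, stops the
    simulation early once the count reaches it (the clade has then escaped
    the absorbing boundary for practical purposes; the outcome is
    ``"surviving"``) — without a cap, supercritical survivors grow
    exponentially and exhaust memory at large ``t_max``.
    """
    if n0 < 1:
        raise ValueError("n0 must be at least 1")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = _rng(seed)
    lam, mu = params.lambda_, params.mu
    total = lam + mu
    p_birth = lam / total
    t, n = 0.0, int(n0)
    times = [0.0]
    counts = [n]
    while n > 0 and (n_cap is None or n < n_cap):
        t += rng.exponential(1.0 / (n * total))
        if t > t_max:
            break
        n += 1 if rng.random() < p_birth else -1
        times.append(t)
        counts.append(n)
    outcome = "extinct" if n == 0 else "surviving"
    return Trajectory(np.asarray(times), np.asarray(counts, dtype=np.int64), outcome)


# ---------------------------------------------------------------------------
# conditioned Yule trees


def sample_branching_ages(
    n_events: int, age: float, birth_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. branching ages of an age/size-conditioned Yule clade.

    Inverse-CDF draw from the truncated exponential on (0, age):
    ``x = T - ln(1 + u*(e^{lam*T} - 1)) / lam``.
    """
    u = rng.random(n_events)
    lam_t = birth_rate * age
    # log1p(u*expm1(lam*T)) keeps precision for both tiny and large lam*T
    return age - np.log1p(u * np.expm1(lam_t)) / birth_rate


def _grow_subtree(
    tip_ids: list[int],
    ages_desc: np.ndarray,
    next_internal: int,
    parent: np.ndarray,
    children: np.ndarray,
    node_ages: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Grow one founder lineage into len(tip_ids) tips.

    Branching ages (descending) split a uniformly chosen extant lineage.
    Returns the id of the subtree root (the founder lineage's final node).
    Tip ids are assigned to lineages at the end, uniformly at random.
    """
    k = len(tip_ids)
    if k == 1:
        return tip_ids[0]
    # An extant lineage is an unfilled child slot of an already-created
    # internal node; each branching (descending age order) turns a uniformly
    # chosen open slot into a new internal node with two open slots of its own.
    v = next_internal  # the founder's first branching: subtree root
    next_internal += 1
    node_ages[v] = ages_desc[0]
    pending = [v]
    open_child_slots: dict[int, int] = {v: 2}
    for i in range(1, k - 1):
        w = next_internal
        next_internal += 1
        node_ages[w] = ages_desc[i]
        choices = [nd for nd in pending for _ in range(open_child_slots[nd])]
        par = choices[rng.integers(len(choices))]
        parent[w] = par
        _attach(children, par, w)
        open_child_slots[par] -= 1
        if open_child_slots[par] == 0:
            pending.remove(par)
        pending.append(w)
        open_child_slots[w] = 2
    # remaining open slots become the tips, assigned in random order
    slots = [nd for nd in pending for _ in range(open_child_slots[nd])]
    for slot_parent, j in zip(slots, rng.permutation(k)):
        tip = tip_ids[int(j)]
        parent[tip] = slot_parent
        _attach(children, slot_parent, tip)
    return v


def _attach(children: np.ndarray, par: int, child: int) -> None:
    if children[par, 0] == NO_NODE:
        children[par, 0] = child
    else:
        children[par, 1] = child


def simulate_yule_conditioned(
    spec: YuleCladeSpec, seed: int | np.random.Generator | None = None
) -> UltrametricTree:
    """Draw an ultrametric Yule tree conditioned on age and tip count.

    For ``n_founders=2`` the root sits exactly at ``spec.age`` and each root
    child founds an age-``T`` conditioned subclade whose size is the uniform
    root split; for ``n_founders=1`` the single founder starts at
    ``spec.age`` (recorded as ``origin_age``) and the returned root is the
    first branching event.
    """
    rng = _rng(seed)
    n, T, lam, f = spec.n_tips, spec.age, spec.birth_rate, spec.n_founders
    M = 2 * n - 1
    parent = np.full(M, NO_NODE, dtype=np.int64)
    children = np.full((M, 2), NO_NODE, dtype=np.int64)
    node_ages = np.zeros(M)
    tip_labels = [f"t{i + 1}" for i in range(n)]
    next_internal = n

    if f == 2:
        if n == 2:
            root = n
            node_ages[root] = T
            for tip in (0, 1):
                parent[tip] = root
                _attach(children, root, tip)
            return UltrametricTree(parent, children, node_ages, tip_labels)
        k = int(rng.integers(1, n))  # tips on the first root child
        ages = np.sort(sample_branching_ages(n - 2, T, lam, rng))[::-1]
        # partition the i.i.d. ages between the two sides at random:
        # side with k tips needs k-1 of them
        idx = rng.permutation(n - 2)
        ages_a = np.sort(ages[idx[: k - 1]])[::-1]
        ages_b = np.sort(ages[idx[k - 1 :]])[::-1]
        root = n
        node_ages[root] = T
        next_internal = n + 1
        ra = _grow_or_tip(list(range(k)), ages_a, next_internal, parent, children, node_ages, rng)
        next_internal += max(k - 1, 0)
        rb = _grow_or_tip(
            list(range(k, n)), ages_b, next_internal, parent, children, node_ages, rng
        )
        for child in (ra, rb):
            parent[child] = root
            _attach(children, root, child)
        return UltrametricTree(parent, children, node_ages, tip_labels)

    # f == 1: stem conditioning; all n-1 branching ages free on (0, T)
    if n == 1:
        raise ValueError("a one-tip tree has no branching structure to return")
    ages = np.sort(sample_branching_ages(n - 1, T, lam, rng))[::-1]
    root = _grow_or_tip(list(range(n)), ages, next_internal, parent, children, node_ages, rng)
    return UltrametricTree(parent, children, node_ages, tip_labels, origin_age=T)


def _grow_or_tip(tip_ids, ages_desc, next_internal, parent, children, node_ages, rng):
    if len(tip_ids) == 1:
        return tip_ids[0]
    return _grow_subtree(tip_ids, ages_desc, next_internal, parent, children, node_ages, rng)


def simulate_yule_forward(
    birth_rate: float,
    age: float,
    n_founders: int = 2,
    seed: int | np.random.Generator | None = None,
) -> tuple[int, np.ndarray]:
    """Plain forward Yule simulation for ``age`` Myr from ``n_founders`` lineages.

    Returns the final tip count and the branching ages (Myr before present,
    excluding the founding of the clade itself).  This is the unconditioned
    process; used as the rejection-sampling oracle for the conditioned
    simulator and for checking the analytic clade-size distributions.
    """
    rng = _rng(seed)
    t = 0.0
    n = n_founders
    branch_times: list[float] = []
    while True:
        t += rng.exponential(1.0 / (birth_rate * n))
        if t > age:
            break
        n += 1
        branch_times.append(t)
    return n, age - np.asarray(branch_times)


# ---------------------------------------------------------------------------
# deterministic size/rate relations


def expected_clade_size(birth_rate: float, age: float, n_founders: int = 2) -> float:
    """Expected extant species count, ``n_founders * exp(birth_rate * age)``."""
    if birth_rate < 0 or age < 0:
        raise ValueError("birth_rate and age must be non-negative")
    return n_founders * float(np.exp(birth_rate * age))

def rate_for_expected_size(n_expected: float, age: float, n_founders: int = 2) -> float:
    """Birth rate at which a clade of ``age`` Myr expects ``n_expected`` species.

    Inverse of :func:`expected_clade_size`: ``ln(n_expected/n_founders)/age``.
    """
    if n_expected <= n_founders:
        raise ValueError("n_expected must exceed n_founders")
    if age <= 0:
        raise ValueError("age must be positive")
    return float(np.log(n_expected / n_founders) / age)
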