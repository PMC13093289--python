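"""Structured coalescent simulation with serial sampling and HKY sequences.

The genealogy simulator runs the continuous-time structured coalescent
backward in time.  Within a population of haploid size N, k active lineages
coalesce at total rate k(k-1)/(2N) per generation.  Lineages enter the
process at their sampling age (serial sampling of ancient material);
divergence events merge a daughter population's lineages into the parent;
admixture pulses move each recipient lineage to the donor with probability
r; founder bottlenecks substitute a reduced size Nb during the db
generations ending at the divergence.

Sequences evolve under HKY with continuous gamma rate variation among sites
and a proportion of invariable sites.  Transition probabilities use the
exact matrix exponential of the normalised HKY rate matrix (via its
symmetric eigendecomposition), so multiple hits at a site are handled
exactly rather than by mutation-event placement.

``summarize`` computes the fixed-order summary-statistic vector shared by
the observed data and every simulated dataset (one code path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scenarios import DemographicScenario, ParameterDraw, ScenarioError
from .seqdata import Alignment


class SimulationError(RuntimeError):
    """Raised when a scenario fails to coalesce (validation should prevent)."""


# --------------------------------------------------------------------------
# genealogy
# --------------------------------------------------------------------------


@dataclass
class Genealogy:
    """Binary coalescent tree over sampled lineages.

    Nodes 0..n-1 are leaves (in sample order); internal nodes follow in
    coalescence order; the last node is the root.  Times are in generations
    before present; leaves sit at their sampling age.
    """

    parent: np.ndarray  # int, -1 at root
    time: np.ndarray  # float, per node
    leaf_pops: list[str]
    leaf_ages: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_pops)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 at root)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def pairwise_tmrca(self, i: int, j: int) -> float:
        """Time of the most recent common ancestor of leaves i and j."""
        anc = set()
        a = i
        while a != -1:
            anc.add(a)
            a = int(self.parent[a])
        a = j
        while a not in anc:
            a = int(self.parent[a])
        return float(self.time[a])

    def to_newick(self) -> str:
        ch = self.children()

        def rec(node: int) -> str:
            p = int(self.parent[node])
            length = (self.time[p] - self.time[node]) if p >= 0 else 0.0
            if ch[node]:
                inner = ",".join(rec(c) for c in ch[node])
                return f"({inner}):{length:.6g}"
            return f"{self.leaf_pops[node]}_{node}:{length:.6g}"

        return rec(self.root) + ";"


def _population_size_profile(scenario, draw):
    """Per-population piecewise-constant size: base Ne plus bottleneck windows."""
    base = {p.label: draw[f"Ne_{p.label}"] for p in scenario.populations}
    windows = {}  # pop -> (start, end, Nb), backward-time window
    for ev in scenario.events:
        if ev.kind != "bottleneck":
            continue
        pop = ev.participants[0]
        if ev.time is not None:
            t_end = draw[f"t_{ev.name}"]
        else:
            div = scenario.divergence_of(pop)
            if div is None:
                raise ScenarioError(f"bottleneck {ev.name}: no divergence for {pop}")
            t_end = draw[f"t_{div.name}"]
        db = draw[f"db_{ev.name}"]
        windows.setdefault(pop, []).append((max(0.0, t_end - db), t_end, draw[f"Nb_{ev.name}"]))

    def size(pop: str, t: float) -> float:
        for lo, hi, nb in windows.get(pop, []):
            if lo <= t < hi:
                return nb
        return base[pop]

    boundary_times = sorted({b for w in windows.values() for lo, hi, _ in w for b in (lo, hi)})
    return size, boundary_times


def simulate_genealogy(
    scenario: DemographicScenario, draw: ParameterDraw, rng: np.random.Generator
) -> Genealogy:
    """Simulate one genealogy under the structured coalescent.

    Event-driven: between breakpoints (sampling ages, event times,
    bottleneck boundaries) sizes are constant, so waiting times are
    exponential with total rate sum_p k_p(k_p-1)/(2 N_p).
    """
    pops = scenario.populations
    leaf_pops: list[str] = []
    leaf_ages: list[float] = []
    for p in pops:
        leaf_pops += [p.label] * p.sample_size
        leaf_ages += [float(p.sampling_age)] * p.sample_size
    n = len(leaf_pops)
    if n < 2:
        raise SimulationError("need at least two sampled lineages")

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    time = np.zeros(n_nodes)
    time[:n] = leaf_ages
    next_node = n

    size_of, bn_times = _population_size_profile(scenario, draw)

    # timeline of structural breakpoints
    events_at: dict[float, list] = {}
    for ev in scenario.events:
        if ev.kind == "divergence":
            events_at.setdefault(draw[f"t_{ev.name}"], []).append(("divergence", ev))
        elif ev.kind == "admixture":
            events_at.setdefault(draw[f"t_{ev.name}"], []).append(("admixture", ev))
    activation: dict[float, list[int]] = {}
    for i, age in enumerate(leaf_ages):
        activation.setdefault(age, []).append(i)
    breakpoints = sorted(
        set(events_at) | set(activation) | set(bn_times) | {0.0}
    )

    active: dict[str, list[int]] = {p.label: [] for p in pops}
    t = 0.0
    pending = [b for b in breakpoints if b >= 0.0]
    n_active = 0

    def coalesce_within(t_start: float, t_stop: float) -> float:
        """Coalesce within populations on [t_start, t_stop); returns final time."""
        nonlocal next_node, n_active
        t_cur = t_start
        while True:
            rates = {
                lab: len(lin) * (len(lin) - 1) / (2.0 * size_of(lab, t_cur))
                for lab, lin in active.items()
                if len(lin) >= 2
            }
            total = sum(rates.values())
            if total <= 0.0:
                return t_stop
            w = rng.exponential(1.0 / total)
            if not np.isfinite(t_stop) or t_cur + w < t_stop:
                t_cur += w
                labels = list(rates)
                probs = np.array([rates[lab] for lab in labels]) / total
                lab = labels[rng.choice(len(labels), p=probs)]
                lin = active[lab]
                i, j = rng.choice(len(lin), size=2, replace=False)
                a, b = lin[i], lin[j]
                node = next_node
                next_node += 1
                parent[a] = parent[b] = node
                time[node] = t_cur
                for x in sorted((i, j), reverse=True):
                    lin.pop(x)
                lin.append(node)
                n_active -= 1
                if n_active == 1:
                    return t_cur
            else:
                return t_stop

    for idx, tb in enumerate(pending):
        t = coalesce_within(t, tb)
        if n_active == 1 and not any(
            kind == "divergence" for b in pending[idx:] for kind, _ in events_at.get(b, [])
        ):
            pass  # fully coalesced; remaining breakpoints are inert
        # structural changes at tb
        for i in activation.get(tb, []):
            active[leaf_pops[i]].append(i)
            n_active += 1
        for kind, ev in events_at.get(tb, []):
            if kind == "divergence":
                daughter, parent_pop = ev.participants
                active[parent_pop].extend(active[daughter])
                active[daughter] = []
            elif kind == "admixture":
                recipient, donor = ev.participants
                r = draw[f"r_{ev.name}"]
                stay, move = [], []
                for lin in active[recipient]:
                    (move if rng.random() < r else stay).append(lin)
                active[recipient] = stay
                active[donor].extend(move)
        t = tb

    # final open-ended epoch: everything must sit in populations that can merge
    t = coalesce_within(t, np.inf)
    if n_active != 1:
        occupied = [lab for lab, lin in active.items() if lin]
        raise SimulationError(
            f"scenario {scenario.id} never coalesces: lineages left in {occupied}"
        )
    return Genealogy(parent=parent, time=time, leaf_pops=leaf_pops,
                     leaf_ages=np.array(leaf_ages))


# --------------------------------------------------------------------------
# sequence evolution
# --------------------------------------------------------------------------


@dataclass
class MutationModel:
    """HKY + Gamma + invariable sites.

    mu is the per-site per-generation mutation rate; branch 'distance' for a
    site is mu * t * rate_multiplier with the rate matrix normalised to one
    expected substitution per unit distance.
    """

    mu: float
    kappa: float = 2.0
    pi: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float = np.inf  # gamma shape; inf = equal rates
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("pi must be 4 frequencies summing to 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.kappa <= 0 or (self.alpha is not None and self.alpha <= 0):
            raise ValueError("kappa and alpha must be > 0")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")
        self.pi = tuple(pi)

    def rate_matrix(self) -> np.ndarray:
        """Normalised HKY rate matrix (mean rate 1 at stationarity)."""
        pi = np.asarray(self.pi)
        Q = np.empty((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = (self.kappa if (i, j) in transitions else 1.0) * pi[j]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -float(np.sum(pi * np.diag(Q)))
        return Q / mean_rate

    def eig(self):
        """Symmetric eigendecomposition: P(d) = A diag(exp(w d)) B."""
        pi = np.asarray(self.pi)
        Q = self.rate_matrix()
        sq = np.sqrt(pi)
        S = (Q * sq[:, None]) / sq[None, :]
        w, U = np.linalg.eigh((S + S.T) / 2)
        A = U / sq[:, None]
        B = U.T * sq[None, :]
        return w, A, B

    def site_rates(self, L: int, rng: np.random.Generator) -> np.ndarray:
        """Per-site rate multipliers: 0 w.p. p_inv, else Gamma(alpha, mean 1)."""
        rates = np.ones(L)
        if np.isfinite(self.alpha):
            rates = rng.gamma(self.alpha, 1.0 / self.alpha, size=L)
        if self.p_inv > 0:
            rates[rng.random(L) < self.p_inv] = 0.0
        return rates


def transition_matrices(model: MutationModel, distances: np.ndarray) -> np.ndarray:
    """Exact HKY P(d) for a vector of distances; shape (len(d), 4, 4)."""
    w, A, B = model.eig()
    E = np.exp(np.outer(distances, w))
    P = np.einsum("ij,lj,jk->lik", A, E, B)
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def simulate_sequences(
    genealogy: Genealogy,
    model: MutationModel,
    L: int,
    rng: np.random.Generator,
    sample_ids: list[str] | None = None,
) -> Alignment:
    """Evolve L sites down the genealogy under HKY+Gamma+I.

    Root states are drawn from the stationary frequencies; along each branch
    child states are drawn from the exact transition matrix at distance
    mu * branch_length * site_rate.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rates = model.site_rates(L, rng)
    pi = np.asarray(model.pi)
    n_nodes = genealogy.n_nodes
    states = np.empty((n_nodes, L), dtype=np.int8)
    root = genealogy.root
    states[root] = rng.choice(4, size=L, p=pi)
    children = genealogy.children()
    w, A, B = model.eig()

    # preorder traversal from root
    stack = [root]
    u = rng  # alias
    while stack:
        node = stack.pop()
        for child in children[node]:
            t = genealogy.time[node] - genealogy.time[child]
            d = model.mu * t * rates  # per-site distances
            if np.all(d == 0):
                states[child] = states[node]
            else:
                E = np.exp(np.outer(d, w))
                # row of P(d_l) for each site's parent state: (A[s] * E) @ B
                rows = (A[states[node]] * E) @ B
                np.clip(rows, 0.0, None, out=rows)
                rows /= rows.sum(axis=1, keepdims=True)
                cum = np.cumsum(rows, axis=1)
                r = u.random(L)
                states[child] = (r[:, None] > cum).sum(axis=1)
            stack.append(child)

    n = genealogy.n_leaves
    ids = sample_ids or [f"s{i}" for i in range(n)]
    return Alignment(
        sample_ids=ids,
        pop_labels=list(genealogy.leaf_pops),
        sample_ages=genealogy.leaf_ages.astype(int),
        seqs=states[:n],
    )


# --------------------------------------------------------------------------
# summary statistics
# --------------------------------------------------------------------------


@dataclass
class SummaryVector:
    """Fixed-order named summary statistics with an undefined-value mask.

    Undefined statistics (e.g. Tajima's D with no segregating sites) are
    stored as 0 with mask 1; the mask columns travel with the values so the
    random forests see identical encodings for training and observation.
    """

    names: list[str]
    values: np.ndarray
    mask: np.ndarray

    def to_features(self) -> np.ndarray:
        return np.concatenate([self.values, self.mask])

    def feature_names(self) -> list[str]:
        return self.names + [f"{n}__mask" for n in self.names]


def _tajimas_d(n: int, S: int, pi_mean: float) -> tuple[float, bool]:
    """Tajima's D; returns (value, defined)."""
    if S == 0 or n < 3:
        return 0.0, False
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a2 + a1**2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0, False
    return float((pi_mean - S / a1) / np.sqrt(var)), True


def summary_names(pop_order: list[str]) -> list[str]:
    names = []
    for p in pop_order:
        names += [
            f"nhap_{p}", f"S_{p}", f"pi_{p}", f"pivar_{p}",
            f"privS_{p}", f"tajD_{p}",
        ]
    for i in range(len(pop_order)):
        for j in range(i + 1, len(pop_order)):
            a, b = pop_order[i], pop_order[j]
            names += [f"dxy_{a}_{b}", f"fst_{a}_{b}", f"sharedhap_{a}_{b}"]
    return names


def summarize(alignment: Alignment, pop_order: list[str] | None = None) -> SummaryVector:
    """Summary-statistic vector over populations, in a fixed order.

    Per population: number of haplotypes, segregating sites, mean and
    variance of pairwise differences, private segregating sites, Tajima's D.
    Per population pair: mean between-population pairwise differences (dxy),
    Hudson-type FST = 1 - mean(within)/mean(between), shared haplotype count.
    """
    if not alignment.is_clean:
        raise ValueError("summarize requires a trimmed alignment")
    pops = pop_order or alignment.populations
    labels = np.asarray(alignment.pop_labels)
    seqs = alignment.seqs
    n, L = seqs.shape

    diff = (seqs[:, None, :] != seqs[None, :, :]).sum(axis=2)

    names = summary_names(pops)
    values = []
    mask = []
    pi_by_pop = {}
    idx_by_pop = {p: np.where(labels == p)[0] for p in pops}
    hapsets = {}
    for p in pops:
        idx = idx_by_pop[p]
        k = idx.size
        sub = seqs[idx]
        uniq = np.unique(sub, axis=0) if k else np.empty((0, L))
        hapsets[p] = {tuple(row) for row in uniq}
        nhap = uniq.shape[0]
        seg_p = (sub != sub[0]).any(axis=0) if k else np.zeros(L, bool)
        S = int(seg_p.sum())
        others = np.setdiff1d(np.arange(n), idx)
        if others.size:
            mono_out = ~(seqs[others] != seqs[others[0]]).any(axis=0)
            privS = int((seg_p & mono_out).sum())
        else:
            privS = S
        if k >= 2:
            iu = np.triu_indices(k, 1)
            pdiffs = diff[np.ix_(idx, idx)][iu]
            pi_mean = float(pdiffs.mean())
            pi_var = float(pdiffs.var())
            pi_def = True
        else:
            pi_mean, pi_var, pi_def = 0.0, 0.0, False
        pi_by_pop[p] = (pi_mean, pi_def)
        tajd, tajd_def = _tajimas_d(k, S, pi_mean) if pi_def else (0.0, False)
        values += [nhap, S, pi_mean, pi_var, privS, tajd]
        mask += [0.0, 0.0, 0.0 if pi_def else 1.0, 0.0 if pi_def else 1.0, 0.0,
                 0.0 if tajd_def else 1.0]

    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b = pops[i], pops[j]
            ia, ib = idx_by_pop[a], idx_by_pop[b]
            if ia.size and ib.size:
                dxy = float(diff[np.ix_(ia, ib)].mean())
                dxy_def = True
            else:
                dxy, dxy_def = 0.0, False
            wa, wa_def = pi_by_pop[a]
            wb, wb_def = pi_by_pop[b]
            if dxy_def and wa_def and wb_def and dxy > 0:
                fst = 1.0 - 0.5 * (wa + wb) / dxy
                fst_def = True
            else:
                fst, fst_def = 0.0, False
            shared = len(hapsets[a] & hapsets[b])
            values += [dxy, fst, shared]
            mask += [0.0 if dxy_def else 1.0, 0.0 if fst_def else 1.0, 0.0]

    return SummaryVector(names=names, values=np.array(values, dtype=float),
                         mask=np.array(mask, dtype=float))


def simulate_dataset(
    scenario: DemographicScenario,
    draw: ParameterDraw,
    L: int,
    rng: np.random.Generator,
    mutation: MutationModel | None = None,
) -> Alignment:
    """One end-to-end simulated dataset: genealogy then sequences."""
    if mutation is None:
        mut = dict(scenario.mutation)
        # mu/kappa with priors were sampled into the draw; fixed values fall back
        if "mu" in draw.values:
            mu = draw.values["mu"]
        else:
            mu = float(mut["mu"]) if "mu" in mut else 1e-5
        if "kappa" in draw.values:
            kappa = draw.values["kappa"]
        else:
            kappa = float(mut["kappa"]) if "kappa" in mut else 2.0
        mutation = MutationModel(
            mu=mu,
            kappa=kappa,
            pi=tuple(mut.get("pi", (0.25, 0.25, 0.25, 0.25))),
            alpha=float(mut.get("alpha", np.inf)),
            p_inv=float(mut.get("p_inv", 0.0)),
        )
    tree = simulate_genealogy(scenario, draw, rng)
    return simulate_sequences(tree, mutation, L, rng)
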