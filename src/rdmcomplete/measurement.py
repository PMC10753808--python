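"""Jordan-Wigner measurement simulation for fermionic 2-RDM elements.

Under the Jordan-Wigner encoding (blocked spin-orbital order: all alpha
orbitals ascending, then all beta), each quartet of distinct fermionic
labels ``i, j, k, l`` yields three permutationally unique two-body
expectation values, each a linear combination of the expectations of the
same 8 Pauli strings (X/Y on the four sites with even Y parity, Z fill in
between).  Quartets with repeated labels reduce to smaller Z-containing
string sets; all string tables here are derived symbolically from the
ladder-operator expansion, never hard-coded.

Measuring a Pauli string ``Q`` with ``m`` shots draws the +1 outcome count
from a binomial distribution, giving an unbiased estimate of <Q> with
variance ``(1 + <Q>)(1 - <Q>)/m``.  Simulated measurement of a set of 2-RDM
elements deduplicates strings across quartets, samples each string once,
and reconstructs noisy fermionic elements through the linear tables.

Real wavefunctions are assumed throughout: strings with an odd number of Y
letters have zero expectation and are never measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .completion import SampleSet
from .rdm_model import (
    OneRDM,
    PackedSectorMatrix,
    SAME_SPIN_SECTORS,
    TwoRDM,
    same_spin_pairs,
    sector_dim,
    unpack_sector,
)

__all__ = [
    "PauliString",
    "MeasurementPlan",
    "MeasurementRecord",
    "SpinOrbitalRDMView",
    "pauli_strings_for_quartet",
    "element_string_table",
    "fermionic_to_pauli_expectations",
    "pauli_expectation",
    "sample_pauli",
    "shot_variance",
    "simulate_measurement",
    "average_variance_per_string",
    "total_cost",
    "build_measurement_plan",
    "sector_element_labels",
]

_LETTERS = "IXYZ"

# single-site Pauli products: (a, b) -> (phase, a*b)
_MUL: dict[tuple[int, int], tuple[complex, int]] = {}
for _a in range(4):
    _MUL[(0, _a)] = (1.0 + 0j, _a)
    _MUL[(_a, 0)] = (1.0 + 0j, _a)
    _MUL[(_a, _a)] = (1.0 + 0j, 0)
for _a, _b, _c in [(1, 2, 3), (2, 3, 1), (3, 1, 2)]:
    _MUL[(_a, _b)] = (1j, _c)
    _MUL[(_b, _a)] = (-1j, _c)


@dataclass(frozen=True)
class PauliString:
    """A tensor product of single-site Pauli operators, e.g. ``XZZY``."""

    letters: str

    def __post_init__(self) -> None:
        if any(c not in _LETTERS for c in self.letters):
            raise ValueError(f"invalid Pauli letters {self.letters!r}")

    @property
    def length(self) -> int:
        return len(self.letters)

    @property
    def is_identity(self) -> bool:
        return set(self.letters) <= {"I"}

    @property
    def y_parity(self) -> int:
        return self.letters.count("Y") % 2

    def __str__(self) -> str:
        return self.letters


def _mul_strings(pa: tuple[int, ...], pb: tuple[int, ...]) -> tuple[complex, tuple[int, ...]]:
    phase = 1.0 + 0j
    out = []
    for a, b in zip(pa, pb):
        ph, c = _MUL[(a, b)]
        phase *= ph
        out.append(c)
    return phase, tuple(out)


def _poly_mul(p1: dict, p2: dict) -> dict:
    out: dict[tuple[int, ...], complex] = {}
    for sa, ca in p1.items():
        for sb, cb in p2.items():
            ph, s = _mul_strings(sa, sb)
            out[s] = out.get(s, 0.0) + ca * cb * ph
    return {s: c for s, c in out.items() if abs(c) > 1e-14}


def _ladder_poly(site: int, dagger: bool, n: int) -> dict:
    """JW image of a single ladder operator as a two-string Pauli polynomial.

    ``a_j   = Z_0 ... Z_{j-1} (X_j + iY_j)/2``
    ``a†_j  = Z_0 ... Z_{j-1} (X_j - iY_j)/2``
    (vacuum = all spins up, occupation ``n_j = (1 - Z_j)/2``).
    """
    base = [3] * site + [0] * (n - site)
    sx = tuple(base[:site] + [1] + base[site + 1:][: n - site - 1])
    sy = tuple(base[:site] + [2] + base[site + 1:][: n - site - 1])
    cy = -0.5j if dagger else 0.5j
    return {sx: 0.5 + 0j, sy: cy}


def ladder_monomial_to_pauli(ops: list[tuple[int, bool]], n: int) -> dict:
    """Expand a product of ladder operators (leftmost first) into Pauli strings."""
    poly = {tuple([0] * n): 1.0 + 0j}
    for site, dagger in ops:
        if not 0 <= site < n:
            raise ValueError(f"site {site} outside register of {n}")
        poly = _poly_mul(poly, _ladder_poly(site, dagger, n))
    return poly


# ---------------------------------------------------------------------------
# string tables for fermionic expectations
# ---------------------------------------------------------------------------

def _real_even_table(poly: dict) -> tuple[float, dict[PauliString, float]]:
    """Keep the even-Y real part of an expansion: what a real state can see.

    Returns the identity coefficient and a map over non-identity strings.
    For a real wavefunction, strings with odd Y parity have zero expectation
    and even-Y strings carry the full (real) expectation, so the dropped
    parts never contribute.
    """
    ident = 0.0
    table: dict[PauliString, float] = {}
    for letters, coeff in poly.items():
        if sum(1 for c in letters if c == 2) % 2 == 1:
            continue
        re = float(np.real(coeff))
        if abs(re) < 1e-14:
            continue
        ps = PauliString("".join(_LETTERS[c] for c in letters))
        if ps.is_identity:
            ident += re
        else:
            table[ps] = table.get(ps, 0.0) + re
    return ident, table


@lru_cache(maxsize=None)
def _element_table_cached(ordered: tuple[int, ...], n_spin_orb: int):
    ops = [(ordered[0], True), (ordered[1], True),
           (ordered[2], False), (ordered[3], False)]
    poly = ladder_monomial_to_pauli(ops, n_spin_orb)
    return _real_even_table(poly)


def element_string_table(i: int, k: int, l: int, j: int, n_spin_orb: int
                         ) -> tuple[float, dict[PauliString, float]]:
    """String table of one two-body expectation ``<a†_i a†_k a_l a_j>``.

    Returns ``(c0, {Q: c_Q})`` such that the expectation equals
    ``c0 + sum_Q c_Q <Q>`` for any real wavefunction.
    """
    return _element_table_cached((i, k, l, j), n_spin_orb)


def pauli_strings_for_quartet(i: int, j: int, k: int, l: int,
                              n_spin_orb: int) -> dict:
    """Pauli strings and coefficients for a quartet of fermionic labels.

    For four distinct labels the three permutationally unique expectations
    ``<a†_i a†_k a_l a_j>``, ``<a†_i a†_j a_l a_k>`` and
    ``<a†_i a†_l a_j a_k>`` are linear combinations of the same 8 strings.
    Repeated labels reduce the operator set (vanishing orderings get a zero
    table) and yield Z-containing strings, including the identity for pure
    number operators.

    Returns a dict with the orderings, per-ordering identity offsets, and a
    map ``PauliString -> length-3 coefficient vector``.
    """
    idx = (i, j, k, l)
    for a in idx:
        if not 0 <= a < n_spin_orb:
            raise ValueError(f"index {a} outside register of {n_spin_orb}")
    if len(set(idx)) > 4:
        raise ValueError("more than four distinct indices")
    orderings = [(i, k, l, j), (i, j, l, k), (i, l, j, k)]
    tables = []
    for (p, q, r, s) in orderings:
        if p == q or r == s:  # a†a† or aa with equal labels vanishes
            tables.append((0.0, {}))
        else:
            tables.append(element_string_table(p, q, r, s, n_spin_orb))
    strings = sorted({q for _, t in tables for q in t},
                     key=lambda ps: ps.letters)
    coeffs = {
        q: np.array([t.get(q, 0.0) for _, t in tables]) for q in strings
    }
    return {
        "orderings": orderings,
        "identity": np.array([c0 for c0, _ in tables]),
        "coefficients": coeffs,
        "strings": strings,
    }


# ---------------------------------------------------------------------------
# exact expectations from stored RDMs (no statevector required)
# ---------------------------------------------------------------------------

class SpinOrbitalRDMView:
    """Serve spin-orbital RDM elements from packed sectors.

    Spin orbitals follow the blocked Jordan-Wigner order: alpha spatial
    orbitals ``0..n-1`` map to sites ``0..n-1`` and beta to ``n..2n-1``.
    """

    def __init__(self, rdm2: TwoRDM, rdm1: OneRDM):
        self.n = rdm2.n_orb
        self.n_spin_orb = 2 * self.n
        self._d = {"a": np.asarray(rdm1.d_alpha), "b": np.asarray(rdm1.d_beta)}
        self._t = {label: unpack_sector(sec)
                   for label, sec in rdm2.sectors.items()}

    def _spin(self, p: int) -> str:
        return "a" if p < self.n else "b"

    def _sp(self, p: int) -> int:
        return p % self.n

    def one_body(self, p: int, q: int) -> float:
        """``<a†_p a†_q>``-free one-body element ``<a†_p a_q>``."""
        if self._spin(p) != self._spin(q):
            return 0.0
        return float(self._d[self._spin(p)][self._sp(p), self._sp(q)])

    def two_body(self, i: int, k: int, l: int, j: int) -> float:
        """``<a†_i a†_k a_l a_j>`` over spin orbitals, resolved by sector."""
        si, sk, sl, sj = (self._spin(x) for x in (i, k, l, j))
        if sorted((si, sk)) != sorted((sj, sl)):
            return 0.0
        pi, pk, pl, pj = (self._sp(x) for x in (i, k, l, j))
        if si == sk:  # same-spin sector (equals sj == sl here)
            label = "aaaa" if si == "a" else "bbbb"
            if label not in self._t:
                return 0.0
            return float(self._t[label][pi, pk, pj, pl])
        # opposite spins on the creators; canonical abab order is
        # <a†_alpha a†_beta a_beta a_alpha>, i.e. spin pattern (s, s', s', s)
        if si == sl:  # pattern (s, s', s, s'): swap the annihilators
            #  <a†_i a†_k a_l a_j> = -<a†_i a†_k a_j a_l>
            return -self.two_body(i, k, j, l)
        if si == "a":
            return float(self._t["abab"][pi, pk, pj, pl])
        #  <a†_ib a†_ka a_lb a_ja> = <a†_ka a†_ib a_ja a_lb>
        return float(self._t["abab"][pk, pi, pl, pj])


@lru_cache(maxsize=None)
def _normal_order(ops: tuple[tuple[int, bool], ...]) -> tuple:
    """Normal-order a ladder monomial by anticommutation.

    Returns a list of ``(sign, creators, annihilators)`` with creators and
    annihilators each sorted ascending by site (duplicate sites vanish).
    """
    out = []
    work = [(1.0, list(ops))]
    while work:
        coeff, seq = work.pop()
        # find an annihilator immediately left of a creator
        pos = next((t for t in range(len(seq) - 1)
                    if not seq[t][1] and seq[t + 1][1]), None)
        if pos is not None:
            p, q = seq[pos][0], seq[pos + 1][0]
            swapped = seq[:pos] + [seq[pos + 1], seq[pos]] + seq[pos + 2:]
            work.append((-coeff, swapped))
            if p == q:
                work.append((coeff, seq[:pos] + seq[pos + 2:]))
            continue
        # separate and bubble-sort each block, tracking the parity
        creators = [s for s, dg in seq if dg]
        annih = [s for s, dg in seq if not dg]
        sign = coeff
        ok = True
        for block in (creators, annih):
            for a in range(len(block)):
                for b in range(len(block) - 1 - a):
                    if block[b] > block[b + 1]:
                        block[b], block[b + 1] = block[b + 1], block[b]
                        sign = -sign
            if len(set(block)) != len(block):
                ok = False
        if ok:
            out.append((sign, tuple(creators), tuple(annih)))
    return tuple(out)


def _evaluate_monomial(sign: float, creators: tuple[int, ...],
                       annih: tuple[int, ...],
                       view: SpinOrbitalRDMView) -> float:
    if len(creators) != len(annih):
        return 0.0  # not number conserving: zero in any eigenstate of N
    deg = len(creators)
    if deg == 0:
        return sign
    if deg == 1:
        return sign * view.one_body(creators[0], annih[0])
    if deg == 2:
        #  <a†_c1 a†_c2 a_x1 a_x2> with our element convention
        return sign * view.two_body(creators[0], creators[1],
                                    annih[0], annih[1])
    raise ValueError("expectation requires a k-RDM with k > 2")


@lru_cache(maxsize=None)
def _majorana_string(site: int, kind: int, n: int) -> tuple[complex, tuple[int, ...]]:
    """Single Pauli string of the Majorana ``Z..Z X_s`` (kind 0) / ``Z..Z Y_s``."""
    letters = tuple([3] * site + [1 + kind] + [0] * (n - site - 1))
    return 1.0 + 0j, letters


@lru_cache(maxsize=None)
def _string_to_ladder(letters: tuple[int, ...], n: int) -> tuple:
    """Decompose a Pauli string into ladder monomials via its Majorana form.

    The X/Y sites define a product of Majorana operators whose Z fills are
    reproduced automatically; leftover Z letters act as standalone
    ``1 - 2 a†_s a_s`` factors.  Returns ``[(coeff, ops), ...]`` with ops a
    ladder monomial (leftmost first).
    """
    xy_sites = [s for s, c in enumerate(letters) if c in (1, 2)]
    if len(xy_sites) % 2 == 1:
        return ()  # odd Majorana parity: zero expectation for real states
    # find the Majorana kind per site whose product matches the X/Y letters
    target_xy = {s: letters[s] for s in xy_sites}
    match = None
    for bits in range(1 << len(xy_sites)):
        kinds = [(bits >> t) & 1 for t in range(len(xy_sites))]
        phase = 1.0 + 0j
        prod = tuple([0] * n)
        for s, kind in zip(xy_sites, kinds):
            ph, ms = _majorana_string(s, kind, n)
            p2, prod = _mul_strings(prod, ms)
            phase *= ph * p2
        if all(prod[s] == target_xy[s] for s in xy_sites):
            match = (phase, prod, kinds)
            break
    if match is None:  # unreachable: the kind map is bijective per site
        raise RuntimeError("no Majorana decomposition found")
    phase, prod, kinds = match
    extra_z = [s for s in range(n)
               if (letters[s] == 3) != (prod[s] == 3) and s not in xy_sites]
    # letters = (1/phase) * (majorana product) * (Z at extra_z)
    terms = [((1.0 / phase), [])]
    for s, kind in zip(xy_sites, kinds):
        #  gamma_{s,0} = a_s + a†_s ;  gamma_{s,1} = i a†_s - i a_s
        parts = ([(1.0, (s, False)), (1.0, (s, True))] if kind == 0
                 else [(1j, (s, True)), (-1j, (s, False))])
        terms = [(c * pc, ops + [op]) for c, ops in terms
                 for pc, op in parts]
    for s in extra_z:
        #  Z_s = 1 - 2 a†_s a_s
        terms = [t for c, ops in terms
                 for t in ((c, ops), (-2.0 * c, ops + [(s, True), (s, False)]))]
    return tuple((c, tuple(ops)) for c, ops in terms)


def pauli_expectation(string: PauliString, view: SpinOrbitalRDMView) -> float:
    """Exact ``<Q>`` for a real, particle-number-conserving state.

    Computed by inverting the Jordan-Wigner map: the string is decomposed
    into ladder monomials, normal-ordered, and evaluated against the stored
    1- and 2-RDMs.  Raises if the string requires a higher RDM.
    """
    if string.length != view.n_spin_orb:
        raise ValueError("string length does not match the register")
    letters = tuple(_LETTERS.index(c) for c in string.letters)
    total = 0.0
    for coeff, ops in _string_to_ladder(letters, view.n_spin_orb):
        for sign, creators, annih in _normal_order(ops):
            val = _evaluate_monomial(sign, creators, annih, view)
            contrib = coeff * val
            total += float(np.real(contrib))
    return total


# ---------------------------------------------------------------------------
# shot-noise sampling
# ---------------------------------------------------------------------------

def shot_variance(expectation: float, m_shots: int) -> float:
    """Binomial single-string variance ``(1 + <Q>)(1 - <Q>)/m``."""
    return (1.0 + expectation) * (1.0 - expectation) / m_shots


def sample_pauli(expectation: float, m_shots: int,
                 rng: np.random.Generator) -> float:
    """Unbiased shot-noise estimate of ``<Q>`` from ``m`` single shots.

    The +1 outcome count is binomial with success probability
    ``(1 + <Q>)/2``; the estimate is ``2 B/m - 1``.
    """
    if abs(expectation) > 1.0 + 1e-12:
        raise ValueError(f"|<Q>| = {abs(expectation)} exceeds 1")
    if m_shots < 1:
        raise ValueError("at least one shot required")
    p = min(max(0.5 * (1.0 + expectation), 0.0), 1.0)
    b = rng.binomial(m_shots, p)
    return 2.0 * b / m_shots - 1.0


# ---------------------------------------------------------------------------
# measurement plans and the full simulator
# ---------------------------------------------------------------------------

@dataclass
class MeasurementPlan:
    """Everything needed to measure a set of 2-RDM elements.

    ``quartets`` lists the distinct fermionic index quartets (sorted spin-
    orbital tuples); ``strings`` is the deduplicated non-identity string set
    (a string shared by several quartets is measured once); ``element_tables``
    maps each required element (sector label, packed row, packed col) to its
    identity offset and string coefficients.
    """

    n_spin_orb: int
    quartets: list[tuple[int, ...]]
    strings: list[PauliString]
    element_tables: dict[tuple[str, int, int], tuple[float, dict[PauliString, float]]]
    shots_per_string: int
    switch_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.shots_per_string < 0:
            raise ValueError("shots_per_string must be nonnegative")

    @property
    def n_settings(self) -> int:
        return len(self.strings)


@dataclass
class MeasurementRecord:
    string: PauliString
    shots: int
    expectation: float
    estimate: float
    variance: float = field(init=False)

    def __post_init__(self) -> None:
        self.variance = (shot_variance(self.expectation, self.shots)
                         if self.shots > 0 else np.inf)


def sector_element_labels(label: str, n: int, a: int, b: int
                          ) -> tuple[int, int, int, int]:
    """Spin-orbital labels (i, k, l, j) of packed element ``P[a, b]``.

    The element equals ``<a†_i a†_k a_l a_j>`` in the blocked JW order.
    """
    if label in SAME_SPIN_SECTORS:
        pairs = same_spin_pairs(n)
        i, k = pairs[a]
        j, l = pairs[b]
        off = 0 if label == "aaaa" else n
        return (i + off, k + off, l + off, j + off)
    i, k = divmod(a, n)
    j, l = divmod(b, n)
    return (i, k + n, l + n, j)


def build_measurement_plan(
    rdm2: TwoRDM,
    elements: dict[str, SampleSet] | None = None,
    shots_per_string: int = 1,
    switch_cost: float = 0.0,
) -> MeasurementPlan:
    """Assemble the string set for measuring the given packed elements.

    ``elements`` maps sector labels to :class:`SampleSet` over the packed
    matrix; ``None`` measures every unique element of every stored sector.
    """
    n = rdm2.n_orb
    n_so = 2 * n
    tables: dict[tuple[str, int, int], tuple[float, dict[PauliString, float]]] = {}
    strings: set[PauliString] = set()
    quartets: set[tuple[int, ...]] = set()
    for label, sec in rdm2.sectors.items():
        d = sector_dim(label, n)
        if elements is None:
            idx = [(a, b) for a in range(d) for b in range(a + 1)]
        elif label in elements:
            if elements[label].d != d:
                raise ValueError(f"sample set dimension mismatch in {label}")
            idx = list(elements[label].indices)
        else:
            continue
        for (a, b) in idx:
            i, k, l, j = sector_element_labels(label, n, a, b)
            c0, table = element_string_table(i, k, l, j, n_so)
            tables[(label, a, b)] = (c0, table)
            strings.update(table)
            quartets.add(tuple(sorted((i, k, l, j))))
    return MeasurementPlan(
        n_spin_orb=n_so,
        quartets=sorted(quartets),
        strings=sorted(strings, key=lambda s: s.letters),
        element_tables=tables,
        shots_per_string=shots_per_string,
        switch_cost=switch_cost,
    )


def fermionic_to_pauli_expectations(
    rdm2: TwoRDM, rdm1: OneRDM, plan: MeasurementPlan
) -> dict[PauliString, float]:
    """True ``<Q>`` for every string in the plan, from the stored RDMs."""
    view = SpinOrbitalRDMView(rdm2, rdm1)
    return {q: pauli_expectation(q, view) for q in plan.strings}


def simulate_measurement(
    rdm2: TwoRDM,
    rdm1: OneRDM,
    elements: dict[str, SampleSet] | None = None,
    shots_per_string: int = 1000,
    seed: int | None = None,
    switch_cost: float = 0.0,
    expectation_cache: dict[PauliString, float] | None = None,
) -> tuple[dict[str, PackedSectorMatrix], list[MeasurementRecord], MeasurementPlan]:
    """Simulate shot-noise measurement of 2-RDM elements.

    Every required string is measured once with ``shots_per_string`` shots
    (deduplicated across quartets) and noisy fermionic elements are
    reconstructed through the linear tables.  Returns partial noisy sector
    matrices (only measured entries filled, symmetrically), the per-string
    records, and the plan.

    ``expectation_cache`` lets repeated simulations of the *same state*
    reuse true string expectations; it is filled in place.
    """
    if shots_per_string < 1:
        raise ValueError("at least one shot per string required")
    plan = build_measurement_plan(rdm2, elements, shots_per_string,
                                  switch_cost)
    if expectation_cache is None:
        exact = fermionic_to_pauli_expectations(rdm2, rdm1, plan)
    else:
        missing = [q for q in plan.strings if q not in expectation_cache]
        if missing:
            view = SpinOrbitalRDMView(rdm2, rdm1)
            for q in missing:
                expectation_cache[q] = pauli_expectation(q, view)
        exact = expectation_cache
    rng = np.random.default_rng(seed)
    estimates: dict[PauliString, float] = {}
    records: list[MeasurementRecord] = []
    for q in plan.strings:
        est = sample_pauli(exact[q], shots_per_string, rng)
        estimates[q] = est
        records.append(MeasurementRecord(q, shots_per_string, exact[q], est))
    noisy: dict[str, np.ndarray] = {}
    n = rdm2.n_orb
    for (label, a, b), (c0, table) in plan.element_tables.items():
        if label not in noisy:
            d = sector_dim(label, n)
            noisy[label] = np.full((d, d), np.nan)
        val = c0 + sum(c * estimates[q] for q, c in table.items())
        noisy[label][a, b] = val
        noisy[label][b, a] = val
    out = {}
    for label, m in noisy.items():
        filled = np.where(np.isnan(m), 0.0, m)
        sec = PackedSectorMatrix(label, n, filled)
        sec.values = np.where(np.isnan(m), np.nan, sec.values)
        out[label] = sec
    return out, records, plan


def average_variance_per_string(expectations, shots: int = 1) -> float:
    """Mean binomial variance over unique strings at equal shots."""
    vals = [expectations[q] for q in expectations] \
        if isinstance(expectations, dict) else list(expectations)
    if not vals:
        raise ValueError("no string expectations given")
    return float(np.mean([shot_variance(e, shots) for e in vals]))


def total_cost(plan: MeasurementPlan) -> float:
    """Total measurement cost: all shots plus the setting-switch overhead.

    ``cost = sum_Q m_Q + c * (number of distinct measurement settings)``,
    one setting per unique string.
    """
    return (plan.shots_per_string * plan.n_settings
            + plan.switch_cost * plan.n_settings)
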