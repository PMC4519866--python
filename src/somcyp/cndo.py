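"""CNDO/2 semi-empirical SCF engine and hydrogen-abstraction energies.

The regioselectivity model ranks candidate carbons by the energy of
homolytic hydrogen abstraction,

    dH_rxn = E(radical) + E(H atom) - E(parent),

a single-point proxy for the rate-determining abstraction barrier of
P450 hydroxylation.  Parent closed-shell species are treated by a
restricted SCF, the carbon radicals by a spin-unrestricted doublet SCF;
the radical keeps the parent geometry minus the abstracted hydrogen
(no relaxation), so only energy *differences within one molecule* are
meaningful — which is all the ranking uses.

The engine is the classic Pople–Segal CNDO/2 formulation: a minimal
valence basis of Slater s/p orbitals, orbital electronegativities
-(I+A)/2, two-center electron repulsion from s-type Slater densities,
resonance integrals beta_AB = (beta_A + beta_B)/2 * S_mu_nu, and
point-charge core–core repulsion Z_A Z_B / R_AB.  Elements H, C, N, O,
F are covered, plus S and Cl through the sp (no d) second-row extension.

Internally everything runs in atomic units; public energies are hartree
with a kcal/mol conversion helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.signal import convolve2d

from .chemio import HydrogenClass, InputError, Molecule, SomcypError

__all__ = [
    "CndoParameters",
    "ScfResult",
    "AbstractionEnergy",
    "ParameterError",
    "ScfConvergenceError",
    "overlap_matrix",
    "gamma_matrix",
    "scf_energy",
    "hydrogen_atom_energy",
    "abstraction_energy",
    "rank_hydrogen_classes",
    "load_energy_table",
    "HARTREE_EV",
    "HARTREE_KCAL",
    "BOHR_PER_ANGSTROM",
]

HARTREE_EV = 27.211386245988
HARTREE_KCAL = 627.509474
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


class ParameterError(InputError):
    pass


class ScfConvergenceError(SomcypError):
    def __init__(self, message, last_energy=None, trace=None, species=None):
        super().__init__(message)
        self.last_energy = last_energy
        self.trace = trace or []
        self.species = species


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class CndoParameters:
    """Per-element CNDO/2 parameters.

    zeta: Slater exponent of the valence shell (shared by s and p).
    onehalf_ia_ev: orbital electronegativities (I+A)/2 in eV, per s/p.
    beta0_ev: bonding parameter beta0 in eV (negative).
    z_core: valence core charge.
    n_shell: principal quantum number of the valence shell.
    """

    zeta: dict[str, float]
    onehalf_ia_ev: dict[str, dict[str, float]]
    beta0_ev: dict[str, float]
    z_core: dict[str, int]
    n_shell: dict[str, int]

    @classmethod
    def default(cls) -> "CndoParameters":
        return cls(
            zeta={
                "H": 1.2,
                "C": 1.625,
                "N": 1.95,
                "O": 2.275,
                "F": 2.425,
                # second row, Slater-rule exponents
                "S": 1.816667,
                "Cl": 2.033333,
            },
            onehalf_ia_ev={
                "H": {"s": 7.176},
                "C": {"s": 14.051, "p": 5.572},
                "N": {"s": 19.316, "p": 7.275},
                "O": {"s": 25.390, "p": 9.111},
                "F": {"s": 32.272, "p": 11.080},
                "S": {"s": 17.650, "p": 6.989},
                "Cl": {"s": 21.591, "p": 8.708},
            },
            beta0_ev={
                "H": -9.0, "C": -21.0, "N": -25.0, "O": -31.0, "F": -39.0,
                "S": -18.150, "Cl": -22.330,
            },
            z_core={"H": 1, "C": 4, "N": 5, "O": 6, "F": 7, "S": 6, "Cl": 7},
            n_shell={"H": 1, "C": 2, "N": 2, "O": 2, "F": 2, "S": 3, "Cl": 3},
        )

    def check_supported(self, symbols) -> None:
        for sym in symbols:
            if sym not in self.zeta:
                raise ParameterError(
                    f"element {sym!r} is not parameterized "
                    f"(supported: {sorted(self.zeta)})"
                )


_DEFAULT_PARAMS = CndoParameters.default()


# ---------------------------------------------------------------------------
# analytic Slater s/p overlap (prolate spheroidal A/B-function expansion)

def _a_funcs(p: float, kmax: int) -> np.ndarray:
    """A_k(p) = int_1^inf x^k exp(-p x) dx, upward recursion (stable, p>0)."""
    a = np.empty(kmax + 1)
    ep = math.exp(-p)
    a[0] = ep / p
    for k in range(1, kmax + 1):
        a[k] = (ep + k * a[k - 1]) / p
    return a


def _b_funcs(beta: float, kmax: int) -> np.ndarray:
    """B_k(beta) = int_{-1}^{1} x^k exp(-beta x) dx."""
    b = np.empty(kmax + 1)
    if abs(beta) < 2.0:
        # series sum_m (-beta)^m/m! * int x^{k+m}; exact parity closed form
        for k in range(kmax + 1):
            total, term = 0.0, 1.0
            for m in range(60):
                if (k + m) % 2 == 0:
                    total += term * 2.0 / (k + m + 1)
                term *= -beta / (m + 1)
                if abs(term) < 1e-18:
                    break
            b[k] = total
    else:
        eb, emb = math.exp(beta), math.exp(-beta)
        b[0] = (eb - emb) / beta
        for k in range(1, kmax + 1):
            sign = eb if k % 2 else -eb
            b[k] = (k * b[k - 1] + sign - emb) / beta
    return b


def _xy_pow(c1: float, c2: float, n: int) -> np.ndarray:
    """Coefficients of (c1*xi + c2*eta)^n as a 2-D array [xi_pow, eta_pow]."""
    out = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        out[k, n - k] = math.comb(n, k) * c1**k * c2 ** (n - k)
    return out


def _pmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return convolve2d(a, b)


_XI2_MINUS_ETA2 = np.zeros((3, 3))
_XI2_MINUS_ETA2[2, 0] = 1.0
_XI2_MINUS_ETA2[0, 2] = -1.0

_ONE_PLUS_XIETA = np.zeros((2, 2))
_ONE_PLUS_XIETA[0, 0] = 1.0
_ONE_PLUS_XIETA[1, 1] = 1.0

_XIETA_MINUS_ONE = np.zeros((2, 2))
_XIETA_MINUS_ONE[0, 0] = -1.0
_XIETA_MINUS_ONE[1, 1] = 1.0

# (xi^2 - 1)(1 - eta^2)
_PI_FACTOR = np.zeros((3, 3))
_PI_FACTOR[2, 0] = 1.0
_PI_FACTOR[2, 2] = -1.0
_PI_FACTOR[0, 0] = -1.0
_PI_FACTOR[0, 2] = 1.0


def _slater_norm(n: int, zeta: float) -> float:
    return (2 * zeta) ** (n + 0.5) / math.sqrt(math.factorial(2 * n))


def local_overlap(
    na: int, la: int, nb: int, lb: int, m: int, za: float, zb: float, r: float
) -> float:
    """Overlap of two Slater orbitals in the bond-aligned local frame.

    `la`, `lb` in {0, 1}; `m` = 0 (sigma) or 1 (pi).  The z axis points from
    orbital A to orbital B; p_sigma of both orbitals is measured along that
    common axis.  `r` in bohr.  Fully analytic via A/B auxiliary integrals.
    """
    if m == 1 and (la == 0 or lb == 0):
        return 0.0
    half = 0.5 * r
    alpha = half * (za + zb)
    beta = half * (za - zb)

    if la == 0:
        pa = _xy_pow(1.0, 1.0, na - 1)
    elif m == 0:
        pa = _pmul(_xy_pow(1.0, 1.0, na - 2), _ONE_PLUS_XIETA)
    else:
        pa = _xy_pow(1.0, 1.0, na - 2)
    if lb == 0:
        pb = _xy_pow(1.0, -1.0, nb - 1)
    elif m == 0:
        pb = _pmul(_xy_pow(1.0, -1.0, nb - 2), _XIETA_MINUS_ONE)
    else:
        pb = _xy_pow(1.0, -1.0, nb - 2)

    poly = _pmul(_pmul(pa, pb), _XI2_MINUS_ETA2)
    if m == 1:
        poly = _pmul(poly, _PI_FACTOR)

    if la == 0 and lb == 0:
        ang = 0.5
    elif la != lb:
        ang = math.sqrt(3.0) / 2.0
    elif m == 0:
        ang = 1.5
    else:
        ang = 0.75

    pref = _slater_norm(na, za) * _slater_norm(nb, zb) * half ** (na + nb + 1) * ang
    kmax = poly.shape[0] - 1
    jmax = poly.shape[1] - 1
    a = _a_funcs(alpha, kmax)
    b = _b_funcs(beta, jmax)
    return float(pref * np.einsum("ij,i,j->", poly, a, b))


def overlap_matrix(m: Molecule, params: CndoParameters | None = None) -> np.ndarray:
    """Valence-orbital overlap matrix S (unit diagonal, symmetric)."""
    params = params or _DEFAULT_PARAMS
    params.check_supported(m.symbols)
    basis = _basis(m, params)
    n = len(basis)
    coords = m.coords * BOHR_PER_ANGSTROM
    s = np.eye(n)
    atom_orbitals: dict[int, list[int]] = {}
    for idx, orb in enumerate(basis):
        atom_orbitals.setdefault(orb.atom, []).append(idx)
    atoms = sorted(atom_orbitals)
    for ia in atoms:
        for ib in atoms:
            if ib <= ia:
                continue
            rvec = coords[ib] - coords[ia]
            r = float(np.linalg.norm(rvec))
            u = rvec / r
            ea, eb = m.symbols[ia], m.symbols[ib]
            na, nb = params.n_shell[ea], params.n_shell[eb]
            za, zb = params.zeta[ea], params.zeta[eb]
            orbs_a, orbs_b = atom_orbitals[ia], atom_orbitals[ib]
            has_p_a = len(orbs_a) > 1
            has_p_b = len(orbs_b) > 1
            s_ss = local_overlap(na, 0, nb, 0, 0, za, zb, r)
            s_sp = local_overlap(na, 0, nb, 1, 0, za, zb, r) if has_p_b else 0.0
            s_ps = local_overlap(na, 1, nb, 0, 0, za, zb, r) if has_p_a else 0.0
            s_pp_sig = local_overlap(na, 1, nb, 1, 0, za, zb, r) if has_p_a and has_p_b else 0.0
            s_pp_pi = local_overlap(na, 1, nb, 1, 1, za, zb, r) if has_p_a and has_p_b else 0.0

            s[orbs_a[0], orbs_b[0]] = s_ss
            if has_p_b:
                for c in range(3):
                    s[orbs_a[0], orbs_b[1 + c]] = u[c] * s_sp
            if has_p_a:
                for c in range(3):
                    s[orbs_a[1 + c], orbs_b[0]] = u[c] * s_ps
            if has_p_a and has_p_b:
                for c1 in range(3):
                    for c2 in range(3):
                        val = u[c1] * u[c2] * s_pp_sig + (
                            (1.0 if c1 == c2 else 0.0) - u[c1] * u[c2]
                        ) * s_pp_pi
                        s[orbs_a[1 + c1], orbs_b[1 + c2]] = val
            for p in orbs_a:
                for q in orbs_b:
                    s[q, p] = s[p, q]
    return s


# ---------------------------------------------------------------------------
# two-center Coulomb integrals over s-type Slater densities

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)


def _gl(f, a: float, b: float) -> float:
    mid, half = 0.5 * (a + b), 0.5 * (b - a)
    x = mid + half * _GL_NODES
    return float(half * np.dot(_GL_WEIGHTS, f(x)))


@lru_cache(maxsize=None)
def _potential_poly(n: int, zeta: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact potential of a normalized (ns)^2 Slater density.

    Phi(s) = (1 - exp(-q s) P(s)) / s with q = 2 zeta; returns q, the
    coefficients of P (ascending) and of T, the antiderivative polynomial
    with  int exp(-q s) P(s) ds = -exp(-q s) T(s).
    """
    q = 2.0 * zeta
    m = 2 * n
    p = np.zeros(m + 1)
    for j in range(m + 1):
        p[j] += q**j / math.factorial(j)
    for j in range(m):
        p[j + 1] -= q ** (j + 1) / (m * math.factorial(j))
    # T = sum_k P^(k) / q^(k+1)
    t = np.zeros(m + 1)
    deriv = p.copy()
    for k in range(m + 1):
        t[: m + 1 - k] += deriv[: m + 1 - k] / q ** (k + 1)
        deriv = np.polynomial.polynomial.polyder(deriv)
        if deriv.size == 0:
            break
    return q, p, t


def _gamma_pair(na: int, za: float, nb: int, zb: float, r: float) -> float:
    """Coulomb repulsion (hartree) of two unit s-Slater densities, r in bohr.

    Uses the closed-form electrostatic potential of density B, averaged
    over spheres about A analytically, and integrates the radial density
    of A with fixed-order Gaussian quadrature (machine-precision for these
    polynomial-times-exponential integrands).
    """
    a = 2.0 * za
    ma = 2 * na
    ca = a ** (ma + 1) / math.factorial(ma)
    q, p, t = _potential_poly(nb, zb)
    tpoly = np.polynomial.polynomial.Polynomial(t)
    ppoly = np.polynomial.polynomial.Polynomial(p)

    def u_a(x):
        return ca * x**ma * np.exp(-a * x)

    if r < 1e-9:
        def f0(x):
            return u_a(x) * (1.0 - np.exp(-q * x) * ppoly(x)) / x

        upper = 60.0 / min(a, q)
        return _gl(f0, 0.0, upper)

    def avg_phi(x):
        lo, hi = np.abs(r - x), r + x
        integ = np.exp(-q * lo) * tpoly(lo) - np.exp(-q * hi) * tpoly(hi)
        return np.minimum(x, r) / (x * r) - integ / (2.0 * x * r)

    def f(x):
        return u_a(x) * avg_phi(x)

    tail = 60.0 / a
    return _gl(f, 0.0, r) + _gl(f, r, r + tail)


@lru_cache(maxsize=None)
def _gamma_cached(na, za, nb, zb, r_key) -> float:
    # canonical ordering => exact symmetry gamma_AB == gamma_BA
    if (na, za) > (nb, zb):
        na, za, nb, zb = nb, zb, na, za
    return _gamma_pair(na, za, nb, zb, r_key)


def gamma_matrix(m: Molecule, params: CndoParameters | None = None) -> np.ndarray:
    """Atom-pair electron-repulsion matrix gamma_AB in hartree."""
    params = params or _DEFAULT_PARAMS
    params.check_supported(m.symbols)
    n = m.n_atoms
    coords = m.coords * BOHR_PER_ANGSTROM
    g = np.zeros((n, n))
    for ia in range(n):
        ea = m.symbols[ia]
        for ib in range(ia, n):
            eb = m.symbols[ib]
            r = float(np.linalg.norm(coords[ib] - coords[ia]))
            val = _gamma_cached(
                params.n_shell[ea], params.zeta[ea],
                params.n_shell[eb], params.zeta[eb],
                round(r, 12),
            )
            g[ia, ib] = g[ib, ia] = val
    return g


# ---------------------------------------------------------------------------
# SCF

@dataclass(frozen=True)
class _Orbital:
    atom: int
    elem: str
    kind: str  # "s" or "p"


def _basis(m: Molecule, params: CndoParameters) -> list[_Orbital]:
    basis = []
    for i, sym in enumerate(m.symbols):
        basis.append(_Orbital(i, sym, "s"))
        if params.n_shell[sym] >= 2:
            basis.extend(_Orbital(i, sym, "p") for _ in range(3))
    return basis


@dataclass
class ScfResult:
    total_energy: float  # hartree
    electronic_energy: float
    core_repulsion: float
    iterations: int
    converged: bool
    density_trace: float
    orbital_energies: np.ndarray | None = None
    density: np.ndarray | None = None

    @property
    def total_energy_kcal(self) -> float:
        return self.total_energy * HARTREE_KCAL


def _core_matrices(m: Molecule, params: CndoParameters):
    basis = _basis(m, params)
    n_orb = len(basis)
    oa = np.array([orb.atom for orb in basis])
    s = overlap_matrix(m, params)
    g_at = gamma_matrix(m, params)
    z = np.array([params.z_core[sym] for sym in m.symbols], dtype=float)

    u_diag = np.empty(n_orb)
    beta_orb = np.empty(n_orb)
    for k, orb in enumerate(basis):
        ia_ev = params.onehalf_ia_ev[orb.elem][orb.kind]
        gamma_aa = g_at[orb.atom, orb.atom]
        u_diag[k] = -ia_ev / HARTREE_EV - (params.z_core[orb.elem] - 0.5) * gamma_aa
        beta_orb[k] = params.beta0_ev[orb.elem] / HARTREE_EV

    same_atom = oa[:, None] == oa[None, :]
    h = 0.5 * (beta_orb[:, None] + beta_orb[None, :]) * s
    h[same_atom] = 0.0
    # diagonal: U_mu - sum_{B != A} Z_B gamma_AB
    zg = g_at @ z  # includes B = A
    np.fill_diagonal(h, u_diag - (zg[oa] - z[oa] * np.diag(g_at)[oa]))

    gamma_orb = g_at[np.ix_(oa, oa)]
    return basis, oa, s, g_at, z, h, gamma_orb


def _atom_charges(diag: np.ndarray, oa: np.ndarray, n_atoms: int) -> np.ndarray:
    return np.bincount(oa, weights=diag, minlength=n_atoms)


def _density(c: np.ndarray, nocc: int, scale: float) -> np.ndarray:
    occ = c[:, :nocc]
    return scale * occ @ occ.T


def core_hamiltonian(m: Molecule, params: CndoParameters | None = None) -> np.ndarray:
    """One-electron CNDO/2 core matrix H (hartree) over the valence basis."""
    params = params or _DEFAULT_PARAMS
    return _core_matrices(m, params)[5]


def fock_matrix(
    m: Molecule, density: np.ndarray, params: CndoParameters | None = None
) -> np.ndarray:
    """Closed-shell CNDO/2 Fock matrix for a given total density matrix."""
    params = params or _DEFAULT_PARAMS
    basis, oa, s, g_at, z, h, gamma_orb = _core_matrices(m, params)
    p = np.asarray(density, float)
    f = h - 0.5 * p * gamma_orb
    p_at = _atom_charges(np.diag(p), oa, m.n_atoms)
    np.fill_diagonal(
        f, np.diag(h) + (g_at @ p_at)[oa] - 0.5 * np.diag(p) * np.diag(gamma_orb)
    )
    return f


def core_repulsion_energy(m: Molecule, params: CndoParameters | None = None) -> float:
    params = params or _DEFAULT_PARAMS
    coords = m.coords * BOHR_PER_ANGSTROM
    z = [params.z_core[s] for s in m.symbols]
    e = 0.0
    for i in range(m.n_atoms):
        for j in range(i + 1, m.n_atoms):
            e += z[i] * z[j] / float(np.linalg.norm(coords[i] - coords[j]))
    return e


def scf_energy(
    m: Molecule,
    charge: int = 0,
    multiplicity: int = 1,
    params: CndoParameters | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    damping: float = 0.4,
    species: str | None = None,
) -> ScfResult:
    """Converge the CNDO/2 density and return the total energy.

    multiplicity 1 runs a restricted closed-shell SCF, multiplicity 2 a
    spin-unrestricted doublet.  `tol` is the maximum absolute change of any
    density-matrix element between cycles; `damping` mixes that fraction of
    the previous density into each update.  Deterministic for fixed inputs.
    """
    params = params or _DEFAULT_PARAMS
    params.check_supported(m.symbols)
    n_el = int(sum(params.z_core[s] for s in m.symbols)) - charge
    if n_el <= 0:
        raise InputError(f"no electrons left (charge={charge})")
    if multiplicity not in (1, 2):
        raise InputError("multiplicity must be 1 (closed shell) or 2 (doublet)")
    if (n_el % 2 == 0) != (multiplicity == 1):
        raise InputError(
            f"electron count {n_el} inconsistent with multiplicity {multiplicity}"
        )

    basis, oa, s, g_at, z, h, gamma_orb = _core_matrices(m, params)
    n_orb = len(basis)
    n_atoms = m.n_atoms
    e_core = core_repulsion_energy(m, params)

    # initial guess: valence electrons spread evenly over each atom's orbitals
    n_orb_per_atom = np.bincount(oa, minlength=n_atoms).astype(float)
    guess_diag = z[oa] / n_orb_per_atom[oa]
    trace_hist: list[float] = []

    def _coulomb_diag(p_total_diag):
        p_at = _atom_charges(p_total_diag, oa, n_atoms)
        return (g_at @ p_at)[oa]

    if multiplicity == 1:
        p = np.diag(guess_diag)
        nocc = n_el // 2
        e_total = math.nan
        converged = False
        for it in range(1, max_iter + 1):
            f = h - 0.5 * p * gamma_orb
            np.fill_diagonal(
                f, np.diag(h) + _coulomb_diag(np.diag(p)) - 0.5 * np.diag(p) * np.diag(gamma_orb)
            )
            eps, c = np.linalg.eigh(f)
            p_new = _density(c, nocc, 2.0)
            e_el = 0.5 * float(np.sum(p_new * (h + f)))
            e_total = e_el + e_core
            trace_hist.append(e_total)
            delta = float(np.max(np.abs(p_new - p)))
            p = (1.0 - damping) * p_new + damping * p
            if delta <= tol:
                converged = True
                break
        if not converged:
            raise ScfConvergenceError(
                f"SCF failed to converge in {max_iter} iterations "
                f"(last max|dP| > {tol:g})",
                last_energy=e_total, trace=trace_hist, species=species,
            )
        # final consistent quantities
        f = h - 0.5 * p * gamma_orb
        np.fill_diagonal(
            f, np.diag(h) + _coulomb_diag(np.diag(p)) - 0.5 * np.diag(p) * np.diag(gamma_orb)
        )
        eps, c = np.linalg.eigh(f)
        p = _density(c, nocc, 2.0)
        e_el = 0.5 * float(np.sum(p * (h + f)))
        return ScfResult(
            total_energy=e_el + e_core, electronic_energy=e_el,
            core_repulsion=e_core, iterations=it, converged=True,
            density_trace=float(np.trace(p)), orbital_energies=eps, density=p,
        )

    # doublet UHF
    n_alpha = (n_el + 1) // 2
    n_beta = n_el - n_alpha
    p_a = np.diag(guess_diag) * (n_alpha / n_el)
    p_b = np.diag(guess_diag) * (n_beta / n_el)
    e_total = math.nan
    converged = False

    def _fock_spin(p_spin, p_total):
        f = h - p_spin * gamma_orb
        np.fill_diagonal(
            f,
            np.diag(h) + _coulomb_diag(np.diag(p_total))
            - np.diag(p_spin) * np.diag(gamma_orb),
        )
        return f

    for it in range(1, max_iter + 1):
        p_tot = p_a + p_b
        f_a = _fock_spin(p_a, p_tot)
        f_b = _fock_spin(p_b, p_tot)
        eps_a, c_a = np.linalg.eigh(f_a)
        eps_b, c_b = np.linalg.eigh(f_b)
        p_a_new = _density(c_a, n_alpha, 1.0)
        p_b_new = _density(c_b, n_beta, 1.0) if n_beta else np.zeros_like(p_a_new)
        e_el = 0.5 * float(
            np.sum((p_a_new + p_b_new) * h)
            + np.sum(p_a_new * _fock_spin(p_a_new, p_a_new + p_b_new))
            + np.sum(p_b_new * _fock_spin(p_b_new, p_a_new + p_b_new))
        )
        e_total = e_el + e_core
        trace_hist.append(e_total)
        delta = float(
            max(np.max(np.abs(p_a_new - p_a)), np.max(np.abs(p_b_new - p_b)))
        )
        p_a = (1.0 - damping) * p_a_new + damping * p_a
        p_b = (1.0 - damping) * p_b_new + damping * p_b
        if delta <= tol:
            converged = True
            p_a, p_b = p_a_new, p_b_new
            break
    if not converged:
        raise ScfConvergenceError(
            f"open-shell SCF failed to converge in {max_iter} iterations",
            last_energy=e_total, trace=trace_hist, species=species,
        )
    p_tot = p_a + p_b
    f_a = _fock_spin(p_a, p_tot)
    f_b = _fock_spin(p_b, p_tot)
    e_el = 0.5 * float(
        np.sum(p_tot * h) + np.sum(p_a * f_a) + np.sum(p_b * f_b)
    )
    eps_a, _ = np.linalg.eigh(f_a)
    return ScfResult(
        total_energy=e_el + e_core, electronic_energy=e_el,
        core_repulsion=e_core, iterations=it, converged=True,
        density_trace=float(np.trace(p_tot)), orbital_energies=eps_a, density=p_tot,
    )


_H_ATOM_CACHE: dict[int, float] = {}


def hydrogen_atom_energy(params: CndoParameters | None = None) -> float:
    """E(H atom), the fixed engine constant in dH_rxn (hartree)."""
    params = params or _DEFAULT_PARAMS
    key = id(params)
    if key not in _H_ATOM_CACHE:
        m = Molecule(["H"], np.zeros((1, 3)), [], name="H-atom")
        _H_ATOM_CACHE[key] = scf_energy(
            m, charge=0, multiplicity=2, params=params, tol=1e-10,
            species="H atom",
        ).total_energy
    return _H_ATOM_CACHE[key]


# ---------------------------------------------------------------------------
# abstraction energies

@dataclass
class AbstractionEnergy:
    hydrogen_class: HydrogenClass
    delta_h: float  # hartree
    parent_energy: float  # hartree
    radical_energy: float  # hartree, for the most labile member hydrogen
    abstracted_hydrogen: int  # atom index of that hydrogen in the parent

    @property
    def delta_h_kcal(self) -> float:
        return self.delta_h * HARTREE_KCAL


def abstraction_energy(
    m: Molecule,
    cls: HydrogenClass,
    params: CndoParameters | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    parent_result: ScfResult | None = None,
) -> AbstractionEnergy:
    """Hydrogen-abstraction reaction energy for one hydrogen class.

    Each member hydrogen is removed in turn at frozen geometry (single
    point, no relaxation) and the class value is the minimum over members:
    the most labile accessible hydrogen governs the abstraction.
    """
    params = params or _DEFAULT_PARAMS
    charge = int(sum(m.charges))
    if parent_result is None:
        try:
            parent_result = scf_energy(
                m, charge=charge, multiplicity=1, params=params,
                tol=tol, max_iter=max_iter, species=f"parent {m.name}",
            )
        except ScfConvergenceError as err:
            raise ScfConvergenceError(
                f"parent molecule {m.name!r}: {err}", err.last_energy, err.trace,
                species=f"parent {m.name}",
            ) from err
    e_h = hydrogen_atom_energy(params)

    best: tuple[float, float, int] | None = None
    for h_idx in cls.hydrogen_indices:
        if m.symbols[h_idx] != "H":
            raise InputError(
                f"class {cls.class_id}: atom {h_idx} is not a hydrogen"
            )
        radical = m.without_atom(h_idx)
        radical.name = f"{m.name}-radical-C{cls.carbon_index}-H{h_idx}"
        try:
            rad = scf_energy(
                radical, charge=charge, multiplicity=2, params=params,
                tol=tol, max_iter=max_iter, species=radical.name,
            )
        except ScfConvergenceError as err:
            raise ScfConvergenceError(
                f"radical {radical.name!r}: {err}", err.last_energy, err.trace,
                species=radical.name,
            ) from err
        delta = rad.total_energy + e_h - parent_result.total_energy
        if best is None or delta < best[0]:
            best = (delta, rad.total_energy, h_idx)

    delta, e_rad, h_idx = best
    return AbstractionEnergy(
        hydrogen_class=cls, delta_h=delta,
        parent_energy=parent_result.total_energy,
        radical_energy=e_rad, abstracted_hydrogen=h_idx,
    )


def rank_hydrogen_classes(
    m: Molecule,
    classes: list[HydrogenClass],
    params: CndoParameters | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> list[AbstractionEnergy]:
    """Classes in ascending dH_rxn (rank 1 = most labile).

    Ties are broken by lower carbon index.  The parent SCF runs once and
    is shared by every radical evaluation.
    """
    if not classes:
        raise InputError("rank_hydrogen_classes requires at least one class")
    params = params or _DEFAULT_PARAMS
    parent = scf_energy(
        m, charge=int(sum(m.charges)), multiplicity=1, params=params,
        tol=tol, max_iter=max_iter, species=f"parent {m.name}",
    )
    energies = [
        abstraction_energy(m, cls, params, tol, max_iter, parent_result=parent)
        for cls in classes
    ]
    energies.sort(key=lambda e: e.delta_h)
    # engine-equal energies (symmetry images differing only by fp noise)
    # are tied; break ties by lower carbon index
    tie_tol = 1e-9
    out: list[AbstractionEnergy] = []
    group: list[AbstractionEnergy] = []
    for e in energies:
        if group and e.delta_h - group[-1].delta_h > tie_tol:
            group.sort(key=lambda g: g.hydrogen_class.carbon_index)
            out.extend(group)
            group = []
        group.append(e)
    group.sort(key=lambda g: g.hydrogen_class.carbon_index)
    out.extend(group)
    return out


def load_energy_table(path: str | Path) -> dict[int, float]:
    """External-energy mode: per-carbon dH_rxn (hartree) from a TSV file.

    Columns: carbon_index, delta_h_hartree (header optional).  The values
    replace the built-in engine so results from other quantum-chemistry
    packages can drive the predictor.
    """
    table: dict[int, float] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if ln == 1 and not parts[0].lstrip("-").isdigit():
            continue  # header
        try:
            table[int(parts[0])] = float(parts[1])
        except (IndexError, ValueError) as err:
            raise InputError(f"energy table {path}: bad row at line {ln}") from err
    if not table:
        raise InputError(f"energy table {path}: no usable rows")
    return table
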