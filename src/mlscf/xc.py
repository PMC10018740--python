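"""Exchange-correlation functionals with analytic derivatives.

Implements spin-polarized Slater exchange, VWN5 correlation, and the PBE
exchange and correlation GGAs.  Energy densities are written once as sympy
expressions in (rho_a, rho_b, sigma_aa, sigma_ab, sigma_bb); the potentials
v_rho and v_sigma are exact symbolic derivatives, lambdified to vectorized
numpy callables and cached per process.  This guarantees that the Fock
contribution is the exact derivative of the quadrature energy — the
finite-difference consistency the test suite enforces.

Densities below a floor (1e-12) are masked out; spin polarization is
clamped marginally inside |zeta| < 1 to keep the PBE spin-scaling factor
phi differentiable at full polarization.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CACHE: dict[tuple[str, str, float], "XCFunctional"] = {}

_RHO_FLOOR = 1e-12
_SIG_FLOOR = 1e-24


def _build_expressions(exchange: str, correlation: str,
                       exchange_scale: float = 1.0):
    import sympy as sp

    ra, rb, saa, sab, sbb = sp.symbols(
        "ra rb saa sab sbb", positive=True
    )
    n = ra + rb
    zeta = (ra - rb) / n
    exprs = []
    xs = sp.Float(repr(exchange_scale))
    needs_grad = False

    def ex_unif_density(nd):
        # LDA exchange energy per volume of an unpolarized gas of density nd
        return -sp.Rational(3, 4) * (3 / sp.pi) ** sp.Rational(1, 3) * nd ** sp.Rational(4, 3)

    if exchange_scale == 0.0:
        exchange = ""
    if exchange == "slater":
        exprs.append(
            xs * (ex_unif_density(2 * ra) + ex_unif_density(2 * rb)) / 2
        )
    elif exchange == "pbe":
        needs_grad = True
        kappa = sp.Float("0.804")
        mu = sp.Float("0.2195149727645171")
        for r_s, s_s in ((ra, saa), (rb, sbb)):
            nd = 2 * r_s
            grad = 2 * sp.sqrt(s_s)      # |grad of 2*rho_sigma|
            kf = (3 * sp.pi ** 2 * nd) ** sp.Rational(1, 3)
            s = grad / (2 * kf * nd)
            fx = 1 + kappa - kappa / (1 + mu * s ** 2 / kappa)
            exprs.append(xs * ex_unif_density(nd) * fx / 2)
    elif exchange:
        raise KeyError(f"unknown exchange functional '{exchange}'")

    rs = (3 / (4 * sp.pi * n)) ** sp.Rational(1, 3)
    fz = ((1 + zeta) ** sp.Rational(4, 3) + (1 - zeta) ** sp.Rational(4, 3) - 2) / (
        2 ** sp.Rational(4, 3) - 2
    )
    fpp0 = 8 / (9 * (2 ** sp.Rational(4, 3) - 2))

    def pw92_G(rs_, A, a1, b1, b2, b3, b4):
        A, a1, b1, b2, b3, b4 = [sp.Float(str(v)) for v in (A, a1, b1, b2, b3, b4)]
        q = 2 * A * (
            b1 * sp.sqrt(rs_) + b2 * rs_ + b3 * rs_ ** sp.Rational(3, 2)
            + b4 * rs_ ** 2
        )
        return -2 * A * (1 + a1 * rs_) * sp.log(1 + 1 / q)

    def pw92_eps(rs_, zeta_):
        e0 = pw92_G(rs_, 0.031091, 0.21370, 7.5957, 3.5876, 1.6382, 0.49294)
        e1 = pw92_G(rs_, 0.015545, 0.20548, 14.1189, 6.1977, 3.3662, 0.62517)
        mac = -pw92_G(rs_, 0.016887, 0.11125, 10.357, 3.6231, 0.88026, 0.49671)
        return (
            e0
            + mac * fz / fpp0 * (1 - zeta_ ** 4)
            + (e1 - e0) * fz * zeta_ ** 4
        )

    if correlation == "vwn5":
        x = sp.sqrt(rs)

        def vwn_F(A, b, c, x0):
            A, b, c, x0 = [sp.Float(str(v)) for v in (A, b, c, x0)]
            X = x ** 2 + b * x + c
            X0 = x0 ** 2 + b * x0 + c
            Q = sp.sqrt(4 * c - b ** 2)
            at = sp.atan(Q / (2 * x + b))
            return A * (
                sp.log(x ** 2 / X)
                + 2 * b / Q * at
                - b * x0 / X0
                * (sp.log((x - x0) ** 2 / X) + 2 * (b + 2 * x0) / Q * at)
            )

        eps_p = vwn_F(0.0310907, 3.72744, 12.9352, -0.10498)
        eps_f = vwn_F(0.01554535, 7.06042, 18.0578, -0.32500)
        alpha = vwn_F(-1 / (6 * np.pi ** 2), 1.13107, 13.0045, -0.00475840)
        eps_c = (
            eps_p
            + alpha * fz / fpp0 * (1 - zeta ** 4)
            + (eps_f - eps_p) * fz * zeta ** 4
        )
        exprs.append(n * eps_c)
    elif correlation == "pbe":
        needs_grad = True
        beta = sp.Float("0.06672455060314922")
        gamma = (1 - sp.log(2)) / sp.pi ** 2
        phi = ((1 + zeta) ** sp.Rational(2, 3) + (1 - zeta) ** sp.Rational(2, 3)) / 2
        kf = (3 * sp.pi ** 2 * n) ** sp.Rational(1, 3)
        ks = sp.sqrt(4 * kf / sp.pi)
        grad_n = sp.sqrt(saa + 2 * sab + sbb)
        t = grad_n / (2 * phi * ks * n)
        eps_unif = pw92_eps(rs, zeta)
        Aden = sp.exp(-eps_unif / (gamma * phi ** 3)) - 1
        A = beta / gamma / Aden
        t2 = t ** 2
        H = gamma * phi ** 3 * sp.log(
            1 + beta / gamma * t2 * (1 + A * t2) / (1 + A * t2 + A ** 2 * t2 ** 2)
        )
        exprs.append(n * (eps_unif + H))
    elif correlation:
        raise KeyError(f"unknown correlation functional '{correlation}'")

    e_total = sum(exprs) if exprs else sp.Integer(0)
    syms = (ra, rb, saa, sab, sbb)
    derivs = [e_total] + [sp.diff(e_total, s) for s in syms]
    # one lambdified callable for all six outputs, with common-subexpression
    # elimination — the derivatives share most of their tree
    func = sp.lambdify(syms, derivs, modules="numpy", cse=True)
    return func, needs_grad


@dataclass
class XCResult:
    e_density: np.ndarray        # energy per volume at each point
    vrho: tuple                  # (d e / d rho_a, d e / d rho_b)
    vsigma: tuple                # (d e/d s_aa, d e/d s_ab, d e/d s_bb)


class XCFunctional:
    """A (possibly empty) exchange + correlation pair with derivatives.

    ``exchange_scale`` multiplies the DFT exchange term — (1 - c_x) for
    hybrid functionals, per the compact eps_xc = eps_c + (1-c_x) eps_x
    bookkeeping the Fock and energy expressions use.
    """

    def __init__(self, exchange_name: str, correlation_name: str,
                 exchange_scale: float = 1.0):
        self.exchange_name = exchange_name
        self.correlation_name = correlation_name
        self.exchange_scale = exchange_scale
        self._func, self.needs_gradient = _build_expressions(
            exchange_name, correlation_name, exchange_scale
        )

    @property
    def is_null(self) -> bool:
        has_x = self.exchange_name and self.exchange_scale != 0.0
        return not (has_x or self.correlation_name)

    def eval(self, rho_a, rho_b, sigma_aa=None, sigma_ab=None, sigma_bb=None):
        rho_a = np.asarray(rho_a, float)
        rho_b = np.asarray(rho_b, float)
        npts = rho_a.shape[0]
        zeros = lambda: np.zeros(npts)  # noqa: E731
        if self.is_null:
            return XCResult(zeros(), (zeros(), zeros()),
                            (zeros(), zeros(), zeros()))
        n = rho_a + rho_b
        mask = n > _RHO_FLOOR
        # clamp: keep both spins marginally positive so |zeta| < 1
        ra = np.clip(rho_a[mask], _RHO_FLOOR * 0.5, None)
        rb = np.clip(rho_b[mask], _RHO_FLOOR * 0.5, None)
        if self.needs_gradient:
            if sigma_aa is None:
                raise ValueError("GGA functional requires density gradients")
            saa = np.clip(np.asarray(sigma_aa)[mask], _SIG_FLOOR, None)
            sbb = np.clip(np.asarray(sigma_bb)[mask], _SIG_FLOOR, None)
            sab = np.asarray(sigma_ab)[mask]
        else:
            saa = sab = sbb = np.full(ra.shape, _SIG_FLOOR)
        vals = self._func(ra, rb, saa, sab, sbb)
        vals = [np.broadcast_to(np.asarray(v, float), ra.shape) for v in vals]
        out_e = zeros()
        out_e[mask] = vals[0]
        vr = (zeros(), zeros())
        vs = (zeros(), zeros(), zeros())
        vr[0][mask] = vals[1]
        vr[1][mask] = vals[2]
        if self.needs_gradient:
            vs[0][mask] = vals[3]
            vs[1][mask] = vals[4]
            vs[2][mask] = vals[5]
        return XCResult(out_e, vr, vs)


def get_functional(exchange_name: str, correlation_name: str,
                   exchange_scale: float = 1.0) -> XCFunctional:
    key = (exchange_name.lower(), correlation_name.lower(),
           float(exchange_scale))
    if key not in _CACHE:
        _CACHE[key] = XCFunctional(*key)
    return _CACHE[key]
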