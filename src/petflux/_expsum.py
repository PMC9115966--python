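"""Closed-form polynomial-exponential curve algebra.

Internal machinery shared by the input-function and kinetic-model code.
Curves of the form

    f(t) = sum_k  c_k (t - tau)^{p_k} exp(-m_k (t - tau)),   t >= tau
    f(t) = 0,                                                t <  tau

are closed under convolution with decaying exponentials and have
elementary antiderivatives.  Because the three-exponential arterial input
function lives in this family and every compartment-model residue function
is a sum of exponentials, whole-model tissue curves and their exact frame
averages come out in closed form -- no quadrature in the fitting loop.
"""

from __future__ import annotations

import numpy as np

# Rates closer than this (relative) are treated as degenerate when
# convolving, switching to the confluent (extra-power) limit form.
_DEGENERATE_RTOL = 1e-9


class ExpPolySum:
    """Sum of ``c * v**p * exp(-m*v)`` terms in the shifted time v = t - tau."""

    __slots__ = ("coef", "power", "rate", "tau")

    def __init__(self, coef, power, rate, tau=0.0):
        self.coef = np.asarray(coef, dtype=float)
        self.power = np.asarray(power, dtype=int)
        self.rate = np.asarray(rate, dtype=float)
        self.tau = float(tau)
        if not (self.coef.shape == self.power.shape == self.rate.shape):
            raise ValueError("coef, power and rate must have equal length")
        if np.any(self.rate < 0):
            raise ValueError("exponential rates must be >= 0")

    # ------------------------------------------------------------------ eval
    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        v = t - self.tau
        out = np.zeros_like(v)
        pos = v > 0
        if np.any(pos):
            vp = v[pos]
            acc = np.zeros_like(vp)
            for c, p, m in zip(self.coef, self.power, self.rate):
                acc += c * vp**p * np.exp(-m * vp)
            out[pos] = acc
        return out

    # ----------------------------------------------------------- integration
    @staticmethod
    def _antideriv(v, p, m):
        """Antiderivative of v**p * exp(-m v), vanishing at v = 0."""
        v = np.asarray(v, dtype=float)
        if m == 0.0:
            return v ** (p + 1) / (p + 1)
        # I_p = -v^p e^{-mv}/m + (p/m) I_{p-1};  I_0 = (1 - e^{-mv})/m
        e = np.exp(-m * v)
        acc = (1.0 - e) / m
        for q in range(1, p + 1):
            acc = (q * acc - v**q * e) / m
        return acc

    def integral(self, a, b):
        """Exact integral over [a, b] in absolute time t (vectorised in a, b)."""
        a = np.maximum(np.asarray(a, dtype=float) - self.tau, 0.0)
        b = np.maximum(np.asarray(b, dtype=float) - self.tau, 0.0)
        out = np.zeros(np.broadcast(a, b).shape)
        for c, p, m in zip(self.coef, self.power, self.rate):
            out += c * (self._antideriv(b, p, m) - self._antideriv(a, p, m))
        return out

    def cumulative(self, t):
        """Integral from 0 to t."""
        return self.integral(0.0, t)

    def frame_averages(self, starts, ends):
        """Mean value over each [start, end) interval (scanner frame average)."""
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        return self.integral(starts, ends) / (ends - starts)

    # ----------------------------------------------------------- convolution
    def convolve_exp(self, b, amplitude=1.0):
        """Convolution with ``amplitude * exp(-b u)`` (u >= 0), b >= 0.

        Returns a new ExpPolySum with the same onset tau.
        """
        if b < 0:
            raise ValueError("kernel rate must be >= 0")
        coef, power, rate = [], [], []
        for c, p, m in zip(self.coef, self.power, self.rate):
            for tc, tp, tm in _conv_terms(p, m, b):
                coef.append(amplitude * c * tc)
                power.append(tp)
                rate.append(tm)
        return ExpPolySum(coef, power, rate, self.tau)

    # --------------------------------------------------------------- algebra
    def __add__(self, other):
        if not isinstance(other, ExpPolySum):
            return NotImplemented
        if other.tau != self.tau:
            raise ValueError("can only add curves with a common onset time")
        return ExpPolySum(
            np.concatenate([self.coef, other.coef]),
            np.concatenate([self.power, other.power]),
            np.concatenate([self.rate, other.rate]),
            self.tau,
        )

    def scaled(self, factor):
        return ExpPolySum(self.coef * factor, self.power, self.rate, self.tau)


def _conv_terms(p, m, b):
    """Terms of (v^p e^{-m v}) * (e^{-b v}) as [(coef, power, rate), ...].

    Uses J_p(v) = int_0^v u^p e^{-d u} du with d = m - b:
        J_0 = (1 - e^{-d v}) / d
        J_p = (p J_{p-1} - v^p e^{-d v}) / d
    and the result e^{-b v} J_p(v).  The confluent case d ~ 0 gives
    v^{p+1} e^{-m v} / (p + 1).
    """
    d = m - b
    if abs(d) <= _DEGENERATE_RTOL * max(m, b, 1.0):
        return [(1.0 / (p + 1), p + 1, m)]
    # terms carried as dict {(power, which): coef}; which: 0 -> e^{-b v}, 1 -> e^{-m v}
    terms = {(0, 0): 1.0 / d, (0, 1): -1.0 / d}
    for q in range(1, p + 1):
        new = {k: q * c / d for k, c in terms.items()}
        key = (q, 1)
        new[key] = new.get(key, 0.0) - 1.0 / d
        terms = new
    return [(c, pw, b if which == 0 else m) for (pw, which), c in terms.items()]
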