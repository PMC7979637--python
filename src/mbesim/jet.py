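"""First-order forward-mode differentiation over numpy arrays.

A :class:`Jet` carries a value array together with its partial derivatives
with respect to a set of named seed variables.  All constitutive laws in this
package are written once over plain floats/arrays and evaluate unchanged on
jets, which makes every pointwise partial derivative (and hence the assembled
finite-element Jacobian) exact chain-rule calculus rather than a numerical
approximation.

Partials are stored sparsely in a dict keyed by seed name, so expressions that
do not depend on a seed carry no storage for it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Jet", "seed", "value", "partial", "log", "sqrt", "exp", "where"]


def _as_val(x):
    return x.val if isinstance(x, Jet) else x


class Jet:
    """Value plus named first-order partial derivatives."""

    __slots__ = ("val", "d")
    __array_priority__ = 100  # win over ndarray in mixed binary ops

    def __init__(self, val, d=None):
        self.val = np.asarray(val, dtype=float) if np.ndim(val) else float(val)
        self.d = d if d is not None else {}

    # -- helpers ----------------------------------------------------------
    def _combine(self, other, fself, fother):
        d = {}
        for k, v in self.d.items():
            d[k] = fself * v
        if isinstance(other, Jet):
            for k, v in other.d.items():
                if k in d:
                    d[k] = d[k] + fother * v
                else:
                    d[k] = fother * v
        return d

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return Jet(self.val + _as_val(other), self._combine(other, 1.0, 1.0))

    __radd__ = __add__

    def __neg__(self):
        return Jet(-self.val, {k: -v for k, v in self.d.items()})

    def __sub__(self, other):
        return Jet(self.val - _as_val(other), self._combine(other, 1.0, -1.0))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        ov = _as_val(other)
        return Jet(self.val * ov, self._combine(other, ov, self.val))

    __rmul__ = __mul__

    def __truediv__(self, other):
        ov = _as_val(other)
        return Jet(self.val / ov, self._combine(other, 1.0 / ov, -self.val / ov**2))

    def __rtruediv__(self, other):
        # other / self with other a constant or Jet handled via __truediv__
        if isinstance(other, Jet):  # pragma: no cover - dispatch goes to __truediv__
            return other.__truediv__(self)
        inv = Jet(1.0 / self.val, {k: -v / self.val**2 for k, v in self.d.items()})
        return inv * other

    def __pow__(self, n):
        if isinstance(n, Jet):
            raise TypeError("jet exponents are not supported")
        f = n * self.val ** (n - 1)
        return Jet(self.val**n, {k: f * v for k, v in self.d.items()})

    # -- comparisons operate on values ------------------------------------
    def __lt__(self, other):
        return self.val < _as_val(other)

    def __le__(self, other):
        return self.val <= _as_val(other)

    def __gt__(self, other):
        return self.val > _as_val(other)

    def __ge__(self, other):
        return self.val >= _as_val(other)

    def __repr__(self):
        return f"Jet({self.val!r}, wrt={sorted(self.d)})"


def seed(val, name):
    """A jet representing an independent variable called ``name``."""
    val = np.asarray(val, dtype=float)
    return Jet(val, {name: np.ones_like(val) if val.ndim else 1.0})


def value(x):
    """Underlying value of ``x`` whether it is a jet or a plain array."""
    return _as_val(x)


def partial(x, name, like=None):
    """Partial derivative of ``x`` w.r.t. seed ``name`` (zero if absent)."""
    if isinstance(x, Jet):
        p = x.d.get(name)
        if p is not None:
            return p * np.ones_like(np.asarray(x.val, dtype=float))
    ref = _as_val(x) if like is None else like
    return np.zeros_like(np.asarray(ref, dtype=float))


def log(x):
    if isinstance(x, Jet):
        return Jet(np.log(x.val), {k: v / x.val for k, v in x.d.items()})
    return np.log(x)


def sqrt(x):
    if isinstance(x, Jet):
        s = np.sqrt(x.val)
        return Jet(s, {k: 0.5 * v / s for k, v in x.d.items()})
    return np.sqrt(x)


def exp(x):
    if isinstance(x, Jet):
        e = np.exp(x.val)
        return Jet(e, {k: e * v for k, v in x.d.items()})
    return np.exp(x)


def where(cond, a, b):
    """Branchless select usable with jets (derivatives follow the branch)."""
    if not (isinstance(a, Jet) or isinstance(b, Jet)):
        return np.where(cond, a, b)
    av, bv = _as_val(a), _as_val(b)
    d = {}
    keys = set()
    if isinstance(a, Jet):
        keys |= set(a.d)
    if isinstance(b, Jet):
        keys |= set(b.d)
    zero = np.zeros_like(np.where(cond, av, bv))
    for k in keys:
        da = a.d.get(k, zero) if isinstance(a, Jet) else zero
        db = b.d.get(k, zero) if isinstance(b, Jet) else zero
        d[k] = np.where(cond, da, db)
    return Jet(np.where(cond, av, bv), d)
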