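"""Taut-string approximation of a discrete signal inside an epsilon-tube.

Given ``f = (f_1, ..., f_n)`` and a tube half-width ``eps > 0``, the taut
string is the function ``g`` with ``max_i |f_i - g_i| <= eps`` that a string
pulled tight between the tube walls ``f - eps`` and ``f + eps`` would take.
It is piecewise linear, bending only where it touches a wall, and among all
tube-feasible sequences it simultaneously minimises every convex symmetric
functional of the increments - in particular the Euclidean norm of
``diff(g)`` and the l1 norm of the second differences.  Both endpoints are
free inside their tube intervals; by stationarity the string then enters and
leaves horizontally unless a wall forces otherwise.

The construction is the classic corridor walk: from the current anchor
(the last wall contact) the set of feasible straight-line slopes is a wedge
that shrinks as points are read; when it empties, the string must bend at
the wall point that pinched the wedge, which becomes the next anchor.  The
walk is linear time in practice (each bend restarts the scan from the new
anchor, which is adjacent to the pinch for realistic tubes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class TautStringEstimate:
    """Result of :func:`taut_string_estimate`.

    ``knots`` are the indices where the slope of ``g`` may change (wall
    contacts plus both endpoints).  Segment structure is exposed both as
    vectorized arrays (``seg_slopes``, ``seg_lengths``) and as a list of
    ``(start, end, slope)`` triples covering ``[0, n-1]``.
    """

    f: np.ndarray
    epsilon: float
    g: np.ndarray
    knots: np.ndarray

    @property
    def n(self) -> int:
        return self.f.size

    @property
    def seg_slopes(self) -> np.ndarray:
        k = self.knots
        return (self.g[k[1:]] - self.g[k[:-1]]) / (k[1:] - k[:-1])

    @property
    def seg_lengths(self) -> np.ndarray:
        return np.diff(self.knots).astype(float)

    @property
    def segments(self) -> list[tuple[int, int, float]]:
        slopes = self.seg_slopes
        k = self.knots
        return [(int(a), int(b), float(s)) for a, b, s in zip(k[:-1], k[1:], slopes)]


@njit(cache=True)
def _ts_core(lo, hi, g, knots):  # pragma: no cover - numba kernel
    n = lo.shape[0]
    nk = 0

    # ---- phase 1: horizontal entry --------------------------------------
    L = lo[0]
    H = hi[0]
    jL = 0
    jH = 0
    i = 1
    bent = False
    while i < n:
        if lo[i] > L:
            L = lo[i]
            jL = i
        if hi[i] < H:
            H = hi[i]
            jH = i
        if L > H:
            bent = True
            break
        i += 1
    if not bent:
        # a single horizontal line fits the whole tube; the height is left
        # to the caller (depends on the tie-break), signalled by nk == 0
        knots[0] = -1
        return 0

    if jL > jH:  # a rising lower wall pinched: contact on the upper wall
        xa = jH
        ya = hi[jH]
    else:  # contact on the lower wall
        xa = jL
        ya = lo[jL]
    for t in range(0, xa + 1):
        g[t] = ya
    knots[nk] = xa
    nk += 1

    # ---- phase 2: wedge walk between anchors ----------------------------
    while xa < n - 1:
        s_hi = np.inf
        s_lo = -np.inf
        jH = -1
        jL = -1
        i = xa + 1
        bent = False
        while i < n:
            dt = i - xa
            sh = (hi[i] - ya) / dt
            sl = (lo[i] - ya) / dt
            if sh < s_hi:
                s_hi = sh
                jH = i
            if sl > s_lo:
                s_lo = sl
                jL = i
            if s_lo > s_hi:
                if jL < jH:
                    k = jL
                    kv = lo[jL]
                else:
                    k = jH
                    kv = hi[jH]
                slope = (kv - ya) / (k - xa)
                for t in range(xa + 1, k + 1):
                    g[t] = ya + slope * (t - xa)
                xa = k
                ya = kv
                knots[nk] = k
                nk += 1
                bent = True
                break
            i += 1
        if bent:
            continue
        # tail: leave horizontally if allowed, else hug the binding wall
        if s_lo <= 0.0 <= s_hi:
            for t in range(xa + 1, n):
                g[t] = ya
            break
        if s_lo > 0.0:
            k = jL
            kv = lo[jL]
        else:
            k = jH
            kv = hi[jH]
        slope = (kv - ya) / (k - xa)
        for t in range(xa + 1, k + 1):
            g[t] = ya + slope * (t - xa)
        xa = k
        ya = kv
        knots[nk] = k
        nk += 1
    return nk


def taut_string_estimate(f: np.ndarray, epsilon: float) -> TautStringEstimate:
    """Compute the taut-string estimate of ``f`` at tube half-width ``epsilon``.

    Raises :class:`ArgumentError` for ``epsilon <= 0`` or ``len(f) < 2``.
    """
    f = np.ascontiguousarray(np.asarray(f, dtype=float))
    if f.ndim != 1 or f.size < 2:
        raise ArgumentError("f must be a 1-D series with at least 2 samples")
    if not np.isfinite(epsilon) or epsilon <= 0:
        raise ArgumentError(f"epsilon must be a positive number, got {epsilon}")
    if not np.all(np.isfinite(f)):
        raise ArgumentError("f must be finite")

    n = f.size
    lo = f - epsilon
    hi = f + epsilon
    g = np.empty(n)
    kbuf = np.empty(n + 2, dtype=np.int64)
    nk = _ts_core(lo, hi, g, kbuf)

    if nk == 0:
        # fully straight horizontal string: pick the height minimising
        # max|f - g| (the midrange), clamped into the feasible interval
        L, H = lo.max(), hi.min()
        y0 = min(max(0.5 * (f.max() + f.min()), L), H)
        g[:] = y0
        interior = np.empty(0, dtype=np.int64)
    else:
        interior = kbuf[:nk].copy()

    # anchors emerge sorted from the walk; just add the endpoints
    if interior.size and interior[0] == 0:
        interior = interior[1:]
    if interior.size and interior[-1] == n - 1:
        interior = interior[:-1]
    knots = np.concatenate(([0], interior, [n - 1]))
    return TautStringEstimate(f=f, epsilon=float(epsilon), g=g, knots=knots)
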