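"""Selection-coefficient estimation from the rise of an ancestry-specific
allele class over a known number of generations.

The observed quantities are ancestry *dosages* on the diploid [0, 2] scale:
``p0``, the genome-wide mean average dosage (a proxy for the pre-selection
level), and ``p1``, the peak average dosage at the putatively selected locus.
Assuming a constant, effectively infinite population so that allele-frequency
change is deterministic, three single-locus viability models relate the
per-generation selection coefficient ``s`` to the frequency trajectory
``f_n(s)``:

simple
    ``f_{n+1} = f_n (1+s)`` — unnormalized geometric growth. Because both the
    dominance and the additive recursions are bounded above by ``f_n (1+s)``,
    the simple model yields a lower bound on ``s``, available in closed form:
    ``s = exp(log(p1/p0)/n) - 1``. It is scale invariant, so dosages may be
    used directly.
dominance
    heterozygote and favored homozygote both have fitness ``1+s``:
    ``f_{n+1} = f_n (1+s) / (1 + (2 - f_n) f_n s)``.
additive
    heterozygote ``1+s``, favored homozygote ``1+2s``:
    ``f_{n+1} = f_n (1 + s + f_n s) / (1 + 2 f_n s)``.

The dominance and additive recursions act on allele *frequencies*, i.e. half
the dosages. ``f_n(s)`` is strictly increasing in ``s`` for ``f_0 in (0,1)``,
so ``s`` is recovered by interval bisection on the final frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

MODELS = ("simple", "dominance", "additive")

_MAX_BISECT = 200


class SelectionInputError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


def forward_freq(f0: float, s: float, n: int, model: str) -> float:
    """Frequency of the favored allele class after ``n`` generations.

    Iterates the deterministic recursion of ``model`` starting from ``f0``.
    The simple model is unnormalized and may exceed 1; dominance and additive
    trajectories stay in [0, 1].
    """
    if not 0.0 <= f0 <= 1.0:
        raise SelectionInputError(f"f0 must be in [0,1], got {f0}")
    if s < 0:
        raise SelectionInputError(f"s must be non-negative, got {s}")
    if n < 0:
        raise SelectionInputError(f"n must be non-negative, got {n}")
    if model not in MODELS:
        raise SelectionInputError(f"unknown model {model!r}")
    f = float(f0)
    for _ in range(n):
        if model == "simple":
            f = f * (1.0 + s)
        elif model == "dominance":
            f = f * (1.0 + s) / (1.0 + (2.0 - f) * f * s)
        else:  # additive
            f = f * (1.0 + s + f * s) / (1.0 + 2.0 * f * s)
    return f


def s_simple(p0: float, p1: float, n: int = 20) -> float:
    """Closed-form lower-bound estimate ``s = exp(log(p1/p0)/n) - 1``.

    Scale invariant: dosages and frequencies give the same answer.
    """
    if p0 <= 0 or p1 <= p0:
        raise SelectionInputError(
            f"need 0 < p0 < p1 for a positive-selection solution, got p0={p0}, p1={p1}")
    return math.exp(math.log(p1 / p0) / n) - 1.0


@dataclass
class SelectionFit:
    """Result of fitting one selection model to a (p0, p1) dosage pair."""

    p0: float
    p1: float
    generations: int
    model: str
    s_hat: float
    epsilon: float
    bracket: tuple[float, float]
    iterations: int
    residual: float

    @property
    def s_rounded(self) -> float:
        """``s_hat`` at the 3-decimal reporting precision."""
        return round(self.s_hat, 3)


def solve_s(p0: float, p1: float, n: int = 20, model: str = "dominance",
            epsilon: float = 1e-8) -> SelectionFit:
    """Estimate ``s`` from a dosage pair under the given model.

    ``p0`` and ``p1`` are average ancestry dosages on the diploid [0, 2]
    scale. The dominance and additive models halve them to frequencies and
    bisect ``s`` until the model's final frequency is within ``epsilon`` of
    the target; the simple model dispatches to the closed form.
    """
    if model not in MODELS:
        raise SelectionInputError(f"unknown model {model!r}")
    if not (0.0 < p0 < p1 <= 2.0):
        raise SelectionInputError(
            f"need 0 < p0 < p1 <= 2 on the dosage scale, got p0={p0}, p1={p1}")

    if model == "simple":
        s = s_simple(p0, p1, n)
        return SelectionFit(p0, p1, n, model, s, epsilon, (s, s), 0, 0.0)

    f0, target = p0 / 2.0, p1 / 2.0
    if target >= 1.0:
        raise SelectionInputError(
            f"p1/2 = {target} must be < 1 for the {model} model")

    lo, hi = 0.0, 1.0
    for _ in range(64):
        if forward_freq(f0, hi, n, model) > target:
            break
        hi *= 2.0
    else:
        raise SolverError("could not bracket s: target frequency unreachable")

    # f_n(s) is strictly increasing in s, so plain bisection on s converges.
    mid, y = hi, forward_freq(f0, hi, n, model)
    it = 0
    for it in range(1, _MAX_BISECT + 1):
        mid = 0.5 * (lo + hi)
        y = forward_freq(f0, mid, n, model)
        if abs(y - target) < epsilon:
            break
        if y > target:
            hi = mid
        else:
            lo = mid
    else:
        raise SolverError(
            f"bisection did not reach residual {epsilon} in {_MAX_BISECT} steps")
    return SelectionFit(p0, p1, n, model, mid, epsilon, (lo, hi), it,
                        abs(y - target))


def fit_all_models(p0: float, p1: float, n: int = 20,
                   epsilon: float = 1e-8) -> dict[str, SelectionFit]:
    """Fit the simple, dominance and additive models to one dosage pair."""
    return {m: solve_s(p0, p1, n, m, epsilon) for m in MODELS}
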