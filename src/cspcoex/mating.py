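"""Closed-form evaluation of the mating decision tree and expected fecundity.

A female enters the interspecific decision tree with probability ``c`` (niche
overlap).  Inside the tree she encounters males sequentially; an encounter is
conspecific with probability proportional to activity-weighted density
``w = a * N``.  A virgin accepts with the ``p`` probabilities and, by
assumption, keeps encountering males until she has mated once (rejections are
redrawn).  After the first mating she has ``m - 1`` further encounter
opportunities, each a single draw accepted with the ``q`` probabilities; a
rejected or heterospecific opportunity is simply spent.  Under conspecific
sperm precedence she realises full fecundity ``r`` if at least one of her
matings was conspecific, so the quantity of interest is

    P = Pr(at least one conspecific mating among at most m matings).

For the default two-shot mating (``m = 2``) this collapses to the closed form

    P_X = (p_XX + p_XY * q_XX * f_Y) * f_X / (f_X * p_XX + f_Y * p_XY)

with activity-weighted frequencies ``f``.  Expected per-capita fecundity is
then ``E = ((1 - c) + c * P) * r``.
"""

from __future__ import annotations

import warnings

from .params import CommunityParams, CommunityState, MatingProbabilities

__all__ = ["conspecific_mating_probability", "expected_fecundity"]


def _encounter_frequencies(
    state: CommunityState, focal: str, activities: tuple[float, float]
) -> tuple[float, float]:
    """Activity-weighted encounter frequencies (f_own, f_het) for ``focal``."""
    aX, aY = activities
    if aX <= 0.0 or aY <= 0.0:
        raise ValueError("activity weights must be > 0")
    wX = aX * state.NX
    wY = aY * state.NY
    total = wX + wY
    if total == 0.0:
        raise ValueError("mating probability is undefined at the origin (N_X = N_Y = 0)")
    if focal == "X":
        return wX / total, wY / total
    if focal == "Y":
        return wY / total, wX / total
    raise ValueError(f"species label must be 'X' or 'Y', got {focal!r}")


def conspecific_mating_probability(
    probs: MatingProbabilities,
    state: CommunityState,
    focal: str,
    max_matings: int = 2,
    activities: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Probability that a ``focal``-species female mates >= once with a conspecific.

    Parameters
    ----------
    probs:
        Acceptance probabilities of the decision tree.
    state:
        Current community densities; only the (activity-weighted) frequencies
        matter.
    focal:
        ``"X"`` or ``"Y"``.
    max_matings:
        Maximum number of matings per female (>= 1); 2 is the headline
        two-shot model.
    activities:
        Encounter-activity weights (aX, aY) biasing who a female meets.

    Returns
    -------
    float
        P in [0, 1].  Equals 1 whenever no heterospecific males exist and
        the conspecific acceptance probability is positive; equals 0 when
        the focal species is absent.

    Notes
    -----
    The first mating phase redraws rejected encounters, so the first mate is
    conspecific with probability ``f_own * p_con / (f_own * p_con + f_het *
    p_het)``.  If both virgin acceptance probabilities are zero the female
    never mates; this degenerate denominator is flagged with a warning and
    P = 0 is returned.  Each of the ``max_matings - 1`` subsequent encounter
    opportunities independently yields a conspecific mating with probability
    ``f_own * q_con`` (heterospecific acceptances consume a mating slot but,
    under CSP, never rescue fecundity).
    """
    if max_matings < 1:
        raise ValueError(f"max_matings must be >= 1, got {max_matings!r}")
    f_own, f_het = _encounter_frequencies(state, focal, activities)
    p_con, p_het, q_con, _ = probs.for_female(focal)

    P, degenerate = _P_closed(f_own, f_het, p_con, p_het, q_con, max_matings)
    if degenerate:
        warnings.warn(
            "both virgin acceptance probabilities vanish for the realised "
            "frequencies; the female never mates (P = 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    return P


def _P_closed(
    f_own: float,
    f_het: float,
    p_con: float,
    p_het: float,
    q_con: float,
    max_matings: int,
) -> tuple[float, bool]:
    """Scalar kernel for P(>= 1 conspecific mating) at given frequencies.

    Returns ``(P, degenerate)`` where ``degenerate`` marks the guard case
    ``f_own * p_con + f_het * p_het == 0`` (the female never mates).
    """
    denom = f_own * p_con + f_het * p_het
    if denom == 0.0:
        return 0.0, True
    p_first_con = f_own * p_con / denom
    # Absorbing walk over post-first-mating encounter opportunities: success
    # as soon as a conspecific male is met (f_own) and accepted (q_con).
    miss_all = (1.0 - f_own * q_con) ** (max_matings - 1)
    return p_first_con + (1.0 - p_first_con) * (1.0 - miss_all), False


def expected_fecundity(
    params: CommunityParams,
    state: CommunityState,
    max_matings: int = 2,
) -> tuple[float, float]:
    """Expected per-capita reproductive output (E_X, E_Y).

    ``E_i = ((1 - c) + c * P_i) * r`` where ``P_i`` is the conspecific-mating
    probability of species *i* at the current densities.  ``(1 - c) * r`` is
    reproduction outside the zone of interspecific interference; the second
    term is reproduction conditional on entering the decision tree, protected
    by CSP only if a conspecific mating occurs.  Bounds: ``(1 - c) * r <= E_i
    <= r``.  Raises at the origin, where frequencies are undefined.
    """
    activities = (params.aX, params.aY)
    out = []
    for focal in ("X", "Y"):
        own_density = state.NX if focal == "X" else state.NY
        if own_density == 0.0:
            # No focal females exist; P = 0 by the frequency limit.
            P = 0.0
            # Still validate that the state is off the origin.
            _encounter_frequencies(state, focal, activities)
        else:
            P = conspecific_mating_probability(
                params.probs, state, focal, max_matings, activities
            )
        out.append(((1.0 - params.c) + params.c * P) * params.r)
    return out[0], out[1]
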