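"""Stochastic generators: decision-tree walker and synthetic mating sessions.

``simulate_decision_tree`` is an individual-based Monte-Carlo rendering of
the mating decision tree, used as an independent oracle for the closed-form
conspecific-mating probability: each replicate female draws encounters
(conspecific with probability proportional to activity-weighted density),
accepts virgins with the ``p`` probabilities, redraws rejected encounters
until she has mated once, then spends her remaining encounter opportunities
one draw at a time under the ``q`` probabilities.

``simulate_sessions`` emulates the statistical structure of the Petri-dish
mating trials (one female and one male per session): a male attempt occurs
with a per-cell Bernoulli probability, the female rejects it with a
per-cell probability, and copulation follows an accepted attempt or, with a
coercion probability, a rejected one.

``make_fixtures`` writes the packaged reference tables (behaviour counts and
the comparative species-pair table) as byte-stable CSVs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from ._tables import BEHAVIOR_COUNTS, SPECIES_PAIRS
from .params import CommunityState, MatingProbabilities
from .sdt import SessionRecord

__all__ = [
    "MonteCarloEstimate",
    "simulate_decision_tree",
    "CellDesign",
    "SessionDesignConfig",
    "default_session_design",
    "simulate_sessions",
    "write_sessions_csv",
    "make_fixtures",
]


@dataclass(frozen=True)
class MonteCarloEstimate:
    """A Monte-Carlo probability estimate with its binomial standard error."""

    estimate: float
    se: float
    n_rep: int


def simulate_decision_tree(
    probs: MatingProbabilities,
    state: CommunityState,
    focal: str,
    max_matings: int = 2,
    n_rep: int = 100_000,
    seed: int | None = None,
    activities: tuple[float, float] = (1.0, 1.0),
) -> MonteCarloEstimate:
    """Monte-Carlo estimate of P(>= 1 conspecific mating) for a focal female.

    Each replicate walks the decision tree individually: the first mating
    phase redraws rejected encounters (a female mates after any number of
    rejections), then each of the remaining ``max_matings - 1`` encounter
    opportunities is a single draw, accepted with the once-mated ``q``
    probabilities; the walk stops once ``max_matings`` matings have
    occurred.  Success is at least one conspecific mating.
    """
    if max_matings < 1:
        raise ValueError(f"max_matings must be >= 1, got {max_matings!r}")
    if n_rep < 1:
        raise ValueError(f"n_rep must be >= 1, got {n_rep!r}")
    aX, aY = activities
    wX, wY = aX * state.NX, aY * state.NY
    total = wX + wY
    if total == 0.0:
        raise ValueError("decision tree is undefined at the origin (N_X = N_Y = 0)")
    f_own = (wX if focal == "X" else wY) / total
    p_con, p_het, q_con, q_het = probs.for_female(focal)

    rng = np.random.default_rng(seed)
    success = np.zeros(n_rep, dtype=bool)

    # --- first mating: redraw until acceptance -----------------------------
    mated = np.zeros(n_rep, dtype=bool)
    active = np.ones(n_rep, dtype=bool)
    if f_own * p_con + (1.0 - f_own) * p_het > 0.0:
        for _ in range(10_000):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            con = rng.random(idx.size) < f_own
            accept_p = np.where(con, p_con, p_het)
            accepted = rng.random(idx.size) < accept_p
            hit = idx[accepted]
            mated[hit] = True
            success[hit] = con[accepted]
            active[hit] = False
    # Replicates still active never mate (acceptance probability ~ 0).

    # --- subsequent encounter opportunities --------------------------------
    matings = mated.astype(np.int64)
    open_ = mated.copy()  # females who mated and may still encounter males
    for _ in range(max_matings - 1):
        idx = np.flatnonzero(open_ & (matings < max_matings))
        if idx.size == 0:
            break
        con = rng.random(idx.size) < f_own
        accept_p = np.where(con, q_con, q_het)
        accepted = rng.random(idx.size) < accept_p
        hit = idx[accepted]
        matings[hit] += 1
        success[hit] |= con[accepted]

    est = float(success.mean())
    se = float(np.sqrt(est * (1.0 - est) / n_rep))
    return MonteCarloEstimate(estimate=est, se=se, n_rep=n_rep)


# ---------------------------------------------------------------------------
# synthetic mating sessions


@dataclass(frozen=True)
class CellDesign:
    """Design of one female-species x male-species cell of the experiment."""

    n_sessions: int
    attempt_p: float
    rejection_p: float

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be positive")
        for name in ("attempt_p", "rejection_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class SessionDesignConfig:
    """Per-cell session counts and behaviour probabilities for a trial batch.

    ``cells`` maps (female_species, male_species) to a :class:`CellDesign`.
    ``coercion_p`` is the probability that copulation occurs despite female
    rejection (coercive mating); an accepted attempt always copulates.
    """

    cells: Mapping[tuple[str, str], CellDesign]
    coercion_p: float = 0.2
    year: str = "2014"

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("config must contain at least one cell")
        if not 0.0 <= self.coercion_p <= 1.0:
            raise ValueError(f"coercion_p must lie in [0, 1], got {self.coercion_p!r}")


def default_session_design() -> SessionDesignConfig:
    """A design emulating the short (2014) ladybird experiment.

    Session counts per cell and the attempt probabilities are the observed
    2014 session proportions; rejection probabilities are the observed
    per-attempt rejection proportions of each female species.
    """
    yed, axy = "H. yedoensis", "H. axyridis"
    return SessionDesignConfig(
        cells={
            (yed, yed): CellDesign(145, 30 / 145, 3 / 9),
            (axy, yed): CellDesign(35, 13 / 35, 14 / 47),
            (axy, axy): CellDesign(87, 47 / 87, 7 / 14),
            (yed, axy): CellDesign(42, 10 / 42, 16 / 30),
        },
        coercion_p=0.2,
        year="2014",
    )


def simulate_sessions(
    config: SessionDesignConfig, seed: int | None = None
) -> list[SessionRecord]:
    """Draw a reproducible batch of synthetic mating sessions.

    One attempt opportunity per session: the male attempts with the cell's
    ``attempt_p``; an attempt is rejected with ``rejection_p``; copulation
    follows acceptance, or rejection with probability ``coercion_p``.
    """
    rng = np.random.default_rng(seed)
    records: list[SessionRecord] = []
    for (female, male), cell in config.cells.items():
        n = cell.n_sessions
        attempted = rng.random(n) < cell.attempt_p
        rejected = attempted & (rng.random(n) < cell.rejection_p)
        coerced = rng.random(n) < config.coercion_p
        copulated = attempted & (~rejected | coerced)
        for i in range(n):
            records.append(
                SessionRecord(
                    female_species=female,
                    male_species=male,
                    year=config.year,
                    n_attempts=int(attempted[i]),
                    n_rejections=int(rejected[i]),
                    copulated=bool(copulated[i]),
                )
            )
    return records


def write_sessions_csv(records: list[SessionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["female_species", "male_species", "year", "n_attempts",
             "n_rejections", "copulated"]
        )
        for r in records:
            writer.writerow(
                [r.female_species, r.male_species, r.year, r.n_attempts,
                 r.n_rejections, int(r.copulated)]
            )


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the packaged reference tables to ``outdir`` as byte-stable CSVs.

    Produces ``behavior_counts.csv`` (the contingency counts of both
    behaviours in both experiment years) and ``species_pairs.csv`` (the
    24-pair comparative table).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_path = outdir / "behavior_counts.csv"
    with open(counts_path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["behavior", "year", "species", "hit", "miss", "false_alarm",
             "correct_rejection"]
        )
        writer.writerows(BEHAVIOR_COUNTS)
    pairs_path = outdir / "species_pairs.csv"
    with open(pairs_path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["group", "common_name", "species_pair", "category", "description",
             "references"]
        )
        writer.writerows(SPECIES_PAIRS)
    return {"counts": counts_path, "pairs": pairs_path}
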