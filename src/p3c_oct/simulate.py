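"""Synthetic P3C-OCT cohorts with a single latent maturity parameter.

Each simulated organisation carries a latent P3C maturity ``theta`` in
[0, 1].  The generator couples both halves of the instrument to it:

* **ticks**: every scoreable response code is ticked independently with
  probability ``theta``, so the expected objective score of a question is
  exactly ``10 theta``.  When nothing in an objective part is ticked its
  "None" marker is ticked instead, as a real respondent would.
* **Likert**: one rating per question from a proportional-odds model — a
  standard-logistic latent judgement is cut at fixed points (0.2, 0.4, 0.6,
  0.8, scale 0.15) so that ``theta = 0.5`` centres the distribution on
  "requires some improvement" and the expected rating rises smoothly with
  maturity.

A paired cohort draws ``theta`` once per organisation (Beta-distributed by
default, mean ~0.53, emulating a mid-maturity general-practice cohort of 40
organisations at two timepoints about six months apart), applies an additive
improvement ``delta`` to ``theta`` at the second timepoint (truncated to
[0, 1]), and redraws all response noise independently between timepoints.

Randomness derives from one root seed with per-organisation,
per-timepoint substreams keyed by counter, so growing the cohort never
reshuffles existing organisations and identical configurations reproduce
byte-identical files.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.special import expit

from .instrument import Instrument
from .responses import (
    LIKERT_ORDER,
    LikertRating,
    OrganisationResponse,
    QuestionResponse,
)

#: substantive ratings ordered worst -> best, matching the cutpoint order
_RATINGS_WORST_FIRST: list[LikertRating] = list(reversed(LIKERT_ORDER))
#: default multipliers of the same ratings, worst -> best
_MULTIPLIERS_WORST_FIRST = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])


class SimulationConfig(BaseModel):
    """Study-condition knobs of the generator.

    ``theta`` fixes every organisation's maturity; when ``None`` maturities
    are drawn from ``Beta(theta_alpha, theta_beta)``.
    """

    model_config = ConfigDict(extra="forbid")

    n_orgs: int = 40
    theta: Optional[float] = None
    theta_alpha: float = 5.3
    theta_beta: float = 4.7
    delta: float = 0.05
    likert_cutpoints: tuple[float, float, float, float] = (0.2, 0.4, 0.6, 0.8)
    likert_scale: float = 0.15
    seed: int = 17

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.theta is not None and not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [-1, 1]")
        if self.likert_scale <= 0:
            raise ValueError("likert_scale must be positive")
        if list(self.likert_cutpoints) != sorted(self.likert_cutpoints):
            raise ValueError("likert_cutpoints must be increasing")
        if self.theta_alpha <= 0 or self.theta_beta <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.n_orgs < 1:
            raise ValueError("n_orgs must be >= 1")
        return self


def _org_rng(config: SimulationConfig, org_index: int,
             timepoint_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), org_index, timepoint_index])


def _draw_likert(rng: np.random.Generator, theta: float,
                 config: SimulationConfig) -> LikertRating:
    cum = expit((np.asarray(config.likert_cutpoints) - theta) / config.likert_scale)
    u = rng.random()
    idx = int(np.sum(u >= cum))  # 0 = worst ... 4 = best
    return _RATINGS_WORST_FIRST[idx]


def draw_thetas(config: SimulationConfig, rng: np.random.Generator,
                n: int) -> np.ndarray:
    if config.theta is not None:
        return np.full(n, config.theta)
    return rng.beta(config.theta_alpha, config.theta_beta, size=n)


def simulate_organisation(instr: Instrument, config: SimulationConfig,
                          org_index: int = 0,
                          theta: Optional[float] = None,
                          org_id: Optional[str] = None,
                          timepoint: str = "t1",
                          timepoint_index: int = 0) -> OrganisationResponse:
    """Draw one organisation's full response set.

    Deterministic given ``(config.seed, org_index, timepoint_index)``; the
    maturity defaults to ``config.theta`` (which must then be set) so that a
    paired cohort can pass per-organisation draws explicitly.
    """
    if theta is None:
        if config.theta is None:
            raise ValueError("theta not given and config.theta is unset")
        theta = config.theta
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    org_id = org_id or f"org{org_index:03d}"
    rng = _org_rng(config, org_index, timepoint_index)

    responses: dict[str, QuestionResponse] = {}
    for q in instr.core_questions:
        ticked: set[str] = set()
        for part in q.parts:
            scoreable = [c.code_id for c in part.scoreable_codes]
            hits = rng.random(len(scoreable)) < theta
            part_ticks = {cid for cid, hit in zip(scoreable, hits) if hit}
            if part_ticks:
                ticked |= part_ticks
            else:
                ticked |= {c.code_id for c in part.codes
                           if c.category.value == "none_marker"}
        responses[q.question_id] = QuestionResponse(
            question_id=q.question_id,
            ticked_codes=ticked,
            likert=_draw_likert(rng, theta, config),
        )

    demo_rng = _org_rng(config, org_index, 10_000)
    demographics = {
        "practice_size": str(int(demo_rng.integers(2_000, 20_001))),
        "setting": str(demo_rng.choice(["rural", "suburban", "urban"])),
    }
    return OrganisationResponse(org_id=org_id, timepoint=timepoint,
                                responses=responses, demographics=demographics)


def simulate_cohort(instr: Instrument, config: SimulationConfig,
                    timepoint: str = "t1", timepoint_index: int = 0,
                    thetas: Optional[np.ndarray] = None,
                    ) -> list[OrganisationResponse]:
    """One cohort of ``config.n_orgs`` organisations at a single timepoint."""
    if thetas is None:
        theta_rng = np.random.default_rng([config.seed % (2**31), 2**20])
        thetas = draw_thetas(config, theta_rng, config.n_orgs)
    return [
        simulate_organisation(instr, config, org_index=i, theta=float(thetas[i]),
                              timepoint=timepoint, timepoint_index=timepoint_index)
        for i in range(config.n_orgs)
    ]


def simulate_paired_cohort(instr: Instrument, config: SimulationConfig,
                           ) -> tuple[list[OrganisationResponse],
                                      list[OrganisationResponse]]:
    """Two-timepoint cohort: same organisations, maturity shifted by ``delta``.

    ``theta_t2 = clip(theta_t1 + delta, 0, 1)``; response noise is
    independent between timepoints.
    """
    if config.n_orgs < 2:
        raise ValueError("a paired cohort needs n_orgs >= 2")
    theta_rng = np.random.default_rng([config.seed % (2**31), 2**20])
    thetas = draw_thetas(config, theta_rng, config.n_orgs)
    thetas2 = np.clip(thetas + config.delta, 0.0, 1.0)
    cohort1 = simulate_cohort(instr, config, "t1", 0, thetas)
    cohort2 = simulate_cohort(instr, config, "t2", 1, thetas2)
    return cohort1, cohort2


# ---------------------------------------------------------------------------
# vectorised score-level path

def simulate_total_matrix(instr: Instrument, config: SimulationConfig,
                          thetas: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Instrument totals for many organisations at once, under the default policy.

    Exploits two exact facts about the default scoring policy: the objective
    score of a question depends only on *how many* scoreable codes are ticked
    (``10 k / n`` with ``k ~ Binomial(n, theta)``), and the question total is
    ``objective x (1 + m)`` with ``m`` the Likert multiplier.  The result is
    distributed identically to simulating full response sets and running the
    scoring engine, at a fraction of the cost; used by the power/type-I-error
    estimator.
    """
    thetas = np.asarray(thetas, dtype=float)
    cuts = np.asarray(config.likert_cutpoints)
    totals = np.zeros(thetas.shape)
    core = instr.core_questions
    for q in core:
        n = q.scoreable_count
        k = rng.binomial(n, thetas)
        cum = expit((cuts.reshape((-1,) + (1,) * thetas.ndim) - thetas)
                    / config.likert_scale)
        u = rng.random(thetas.shape)
        idx = np.sum(u >= cum, axis=0)  # 0 worst ... 4 best
        m = _MULTIPLIERS_WORST_FIRST[idx]
        totals += (10.0 * k / n) * (1.0 + m)
    return totals / len(core)
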