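"""Within-subject context-usefulness study: trial plans and analyses.

Each SOI is judged three times per participant, once per highlight strategy
(paragraph only, previous sentence highlighted, LLM highlights).  The trial
order is block-randomized: each strategy of each SOI is randomly assigned to
one of three blocks, SOIs are shuffled within blocks, and whole orders are
rejection-sampled until any two trials of the same SOI are at least
``min_separation`` positions apart (so a participant never sees the same
statement twice in close succession).

Analyses mirror the study report: the 8-way breakdown of which strategy
combinations were deemed useful per SOI, the any-useful rate, pairwise
preference counts, and paired t-tests on per-SOI 0/1 usefulness
differences, optionally conditioned on the paragraph-only judgment.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as _st

from .errors import ConfigurationError, IntegrityError

__all__ = [
    "STRATEGIES",
    "COMBINATIONS",
    "Trial",
    "TrialPlan",
    "Judgment",
    "JudgmentTable",
    "make_trial_plan",
    "check_min_separation",
    "combination_breakdown",
    "any_useful_rate",
    "pairwise_preference_counts",
    "paired_preference_test",
    "PairedTestResult",
]

STRATEGIES = ("none", "previous_sentence", "llm")

#: The 8 combinations of strategies deemed useful for one SOI, keyed by the
#: (llm, previous_sentence, none) truth triple.  "paragraph" = no highlight.
COMBINATIONS: dict[tuple[bool, bool, bool], str] = {
    (True, True, True): "everything",
    (True, False, False): "gpt_only",
    (False, True, False): "ps_only",
    (False, False, True): "paragraph_only",
    (True, True, False): "gpt_and_ps",
    (True, False, True): "gpt_and_paragraph",
    (False, True, True): "ps_and_paragraph",
    (False, False, False): "nothing",
}


@dataclass(frozen=True)
class Trial:
    position: int
    soi_id: str
    strategy: str


@dataclass
class TrialPlan:
    trials: list[Trial]
    n_sois: int
    seed: int
    min_separation: int

    def validate(self) -> None:
        if len(self.trials) != 3 * self.n_sois:
            raise IntegrityError("plan must hold 3 trials per SOI")
        pairs = {(t.soi_id, t.strategy) for t in self.trials}
        sois = {t.soi_id for t in self.trials}
        if len(pairs) != 3 * len(sois):
            raise IntegrityError("each (soi, strategy) pair must occur exactly once")
        if not check_min_separation(self, self.min_separation):
            raise IntegrityError("min-separation constraint violated")


@dataclass(frozen=True)
class Judgment:
    participant_id: str
    soi_id: str
    strategy: str
    useful: bool
    response_ms: int | None = None
    comment: str | None = None


@dataclass
class JudgmentTable:
    judgments: list[Judgment]

    def __post_init__(self):
        keys = [(j.participant_id, j.soi_id, j.strategy) for j in self.judgments]
        if len(set(keys)) != len(keys):
            raise IntegrityError("(participant, soi, strategy) must be unique")

    @property
    def participants(self) -> list[str]:
        return sorted({j.participant_id for j in self.judgments})

    @property
    def sois(self) -> list[str]:
        return sorted({j.soi_id for j in self.judgments})

    def lookup(self, participant: str) -> dict[str, dict[str, bool]]:
        """per-SOI strategy->useful map for one participant; must be complete."""
        out: dict[str, dict[str, bool]] = {}
        for j in self.judgments:
            if j.participant_id == participant:
                out.setdefault(j.soi_id, {})[j.strategy] = j.useful
        missing = [
            (soi, strat)
            for soi, by_strat in out.items()
            for strat in STRATEGIES
            if strat not in by_strat
        ]
        if missing:
            raise IntegrityError(
                f"incomplete coverage for participant {participant!r}: "
                f"missing {missing}"
            )
        if not out:
            raise IntegrityError(f"no judgments for participant {participant!r}")
        return out


# ---------------------------------------------------------------------------
# Trial plan generation
# ---------------------------------------------------------------------------


def check_min_separation(plan: TrialPlan, min_separation: int) -> bool:
    """True iff any two trials of the same SOI are >= min_separation apart."""
    last_seen: dict[str, int] = {}
    for t in sorted(plan.trials, key=lambda t: t.position):
        if t.soi_id in last_seen and t.position - last_seen[t.soi_id] < min_separation:
            return False
        last_seen[t.soi_id] = t.position
    return True


def make_trial_plan(
    soi_ids: list[str],
    seed: int,
    min_separation: int = 5,
    blocks: int = 3,
    max_retries: int = 10_000,
) -> TrialPlan:
    """Block-randomized trial order under the min-separation constraint.

    For each SOI the three strategies are randomly assigned to the three
    blocks (one per block); SOIs are shuffled inside each block; whole
    orders are rejection-sampled until the separation constraint holds.
    Deterministic per seed.
    """
    if blocks != len(STRATEGIES):
        raise ConfigurationError("blocks must equal the number of strategies (3)")
    n = len(soi_ids)
    if n < 2 * min_separation:
        raise ConfigurationError(
            f"need >= {2 * min_separation} SOIs for min_separation="
            f"{min_separation}; got {n}"
        )
    if len(set(soi_ids)) != n:
        raise ConfigurationError("soi_ids must be distinct")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        block_contents: list[list[tuple[str, str]]] = [[] for _ in range(blocks)]
        for soi in soi_ids:
            for b, strat in zip(rng.permutation(blocks), STRATEGIES):
                block_contents[b].append((soi, strat))
        trials: list[Trial] = []
        pos = 0
        for content in block_contents:
            order = rng.permutation(len(content))
            for i in order:
                soi, strat = content[i]
                trials.append(Trial(position=pos, soi_id=soi, strategy=strat))
                pos += 1
        plan = TrialPlan(
            trials=trials, n_sois=n, seed=seed, min_separation=min_separation
        )
        if check_min_separation(plan, min_separation):
            plan.validate()
            return plan
    raise ConfigurationError(
        f"could not satisfy min_separation={min_separation} after "
        f"{max_retries} sampled orders"
    )


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------


def _round1(x: float) -> float:
    """Round half-up to one decimal (table formatting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def combination_breakdown(table: JudgmentTable, participant: str) -> dict[str, float]:
    """Percent of SOIs falling in each of the 8 usefulness combinations.

    Percentages are over the participant's SOIs, rounded half-up to one
    decimal; the 8 values partition the SOIs so they sum to 100 up to
    rounding.
    """
    per_soi = table.lookup(participant)
    counts = {name: 0 for name in COMBINATIONS.values()}
    for by_strat in per_soi.values():
        key = (by_strat["llm"], by_strat["previous_sentence"], by_strat["none"])
        counts[COMBINATIONS[key]] += 1
    n = len(per_soi)
    return {name: _round1(100.0 * c / n) for name, c in counts.items()}


def any_useful_rate(table: JudgmentTable, participant: str) -> float:
    """Percent of SOIs where at least one presentation was useful.

    Identically 100 minus the "nothing" share of the combination breakdown.
    """
    return _round1(100.0 - combination_breakdown(table, participant)["nothing"])


def pairwise_preference_counts(
    table: JudgmentTable, participant: str, strategy_a: str, strategy_b: str
) -> dict[str, int]:
    """2x2 concordance counts of A/B usefulness over the participant's SOIs."""
    per_soi = table.lookup(participant)
    counts = {"a_only": 0, "b_only": 0, "both": 0, "neither": 0}
    for by_strat in per_soi.values():
        a, b = by_strat[strategy_a], by_strat[strategy_b]
        if a and not b:
            counts["a_only"] += 1
        elif b and not a:
            counts["b_only"] += 1
        elif a and b:
            counts["both"] += 1
        else:
            counts["neither"] += 1
    return counts


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float | None
    p_value: float | None
    n_items: int
    degenerate: bool = False
    #: significance flags at the two reporting thresholds
    significant_05: bool = False
    significant_10: bool = False


def paired_preference_test(
    table: JudgmentTable,
    participant: str,
    strategy_a: str,
    strategy_b: str,
    condition: str = "all",
    alternative: str = "two-sided",
) -> PairedTestResult:
    """Paired t-test on per-SOI usefulness differences (A minus B, 0/1 coded).

    ``condition`` filters SOIs by the participant's paragraph-only judgment
    (strategy "none"): "all", "paragraph_useful" or "paragraph_not_useful".
    With fewer than 2 items, or zero variance of the differences, a defined
    degenerate no-test result is returned instead of an exception.
    """
    if condition not in ("all", "paragraph_useful", "paragraph_not_useful"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    per_soi = table.lookup(participant)
    diffs = []
    for by_strat in per_soi.values():
        if condition == "paragraph_useful" and not by_strat["none"]:
            continue
        if condition == "paragraph_not_useful" and by_strat["none"]:
            continue
        diffs.append(int(by_strat[strategy_a]) - int(by_strat[strategy_b]))
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 2 or (np.std(d, ddof=1) == 0.0 and d.mean() == 0.0):
        return PairedTestResult(None, None, n, degenerate=True)
    if np.std(d, ddof=1) == 0.0:
        # constant non-zero difference: the t statistic diverges; report the
        # limit rather than a no-test result
        stat = float(np.sign(d.mean()) * np.inf)
        return PairedTestResult(stat, 0.0, n, significant_05=True,
                                significant_10=True)
    res = _st.ttest_1samp(d, 0.0, alternative=alternative)
    p = float(res.pvalue)
    return PairedTestResult(
        statistic=float(res.statistic),
        p_value=p,
        n_items=n,
        significant_05=p < 0.05,
        significant_10=p < 0.1,
    )
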