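"""Stimulus preference of single units and its split-half reliability.

For each unit, spikes are counted in a half-open response window (default
the full 2 s trial: stimulus + ISI) for every non-probe presentation of each
stimulus. The stimulus with the largest total count is the *preferred*
stimulus; its cyclic sequence neighbours are the *preceding* and *following*
stimuli. Reliability is scored by split-half cross-validation: the preferred
stimulus is chosen on a random half of the iterations and confirmed on the
held-out half when its median response exceeds the median of the other
stimuli's medians (chance level 1/2); a one-sided binomial test on the
confirmation proportion gives the consistency p-value. Consistent cells are
classed *strong* when a one-way ANOVA of counts on stimulus identity is
significant, otherwise *weak*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, NoPreferenceError
from .session import Session

DEFAULT_RESPONSE_WINDOW = (0.0, 2.0)  # seconds from stimulus onset; spans stimulus + ISI


@dataclass
class ResponseTable:
    """Spike counts per (iteration, stimulus) in the response window.

    ``valid`` is False for probe presentations, which are excluded from all
    statistics (the stimulus was not shown on probe trials).
    """

    unit_id: str
    counts: np.ndarray  # (n_iterations, n_stimuli) int
    valid: np.ndarray  # (n_iterations, n_stimuli) bool
    window: tuple[float, float]

    @property
    def n_iterations(self) -> int:
        return self.counts.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.counts.shape[1]

    def masked(self) -> np.ndarray:
        """Float counts with NaN at excluded (probe) entries."""
        m = self.counts.astype(float)
        m[~self.valid] = np.nan
        return m


@dataclass
class CellTuning:
    unit_id: str
    preferred_id: int
    preceding_id: int
    following_id: int
    consistency: float
    consistency_p: float
    tuning_class: str  # {"strong", "weak", "inconsistent"}
    preference_tied: bool = False


def build_response_table(
    session: Session,
    unit_id: str,
    window: tuple[float, float] = DEFAULT_RESPONSE_WINDOW,
) -> ResponseTable:
    """Count each unit's spikes in ``[onset + w0, onset + w1)`` per event."""
    unit = session.get_unit(unit_id)
    t = unit.spike_times_s
    n_it = session.n_iterations
    counts = np.zeros((n_it, session.n_stimuli), dtype=int)
    valid = np.zeros((n_it, session.n_stimuli), dtype=bool)
    w0, w1 = window
    for e in session.events:
        if e.is_probe:
            continue
        lo = np.searchsorted(t, e.onset_s + w0, side="left")
        hi = np.searchsorted(t, e.onset_s + w1, side="left")
        counts[e.iteration_index, e.stimulus_id] = hi - lo
        valid[e.iteration_index, e.stimulus_id] = True
    return ResponseTable(unit_id=unit_id, counts=counts, valid=valid, window=(w0, w1))


def identify_preferred(
    table: ResponseTable, sequence_order: list[int] | None = None
) -> tuple[int, int, int]:
    """Preferred stimulus (argmax of column sums) and its cyclic neighbours.

    Ties go to the lowest stimulus index (with a warning); neighbours are
    taken in presentation order, wrapping around since the sequence repeats
    continually.
    """
    m = table.masked()
    col = np.nansum(m, axis=0)
    if np.nansum(col) == 0:
        raise NoPreferenceError(f"unit {table.unit_id}: no spikes in any response window")
    preferred = int(np.argmax(col))  # argmax takes the first (lowest) index on ties
    if np.sum(col == col[preferred]) > 1:
        warnings.warn(
            f"unit {table.unit_id}: tied preference, choosing stimulus {preferred}",
            stacklevel=2,
        )
    order = sequence_order if sequence_order is not None else list(range(table.n_stimuli))
    pos = order.index(preferred)
    preceding = order[(pos - 1) % len(order)]
    following = order[(pos + 1) % len(order)]
    return preferred, preceding, following


def _split_credit(train: np.ndarray, test: np.ndarray, rng: np.random.Generator | None) -> float:
    """Credit for one split: 1 if the train-half preference is confirmed on
    the test half, 0.5 on an exact tie of the deciding medians."""
    col = np.nansum(train, axis=0)
    best = np.flatnonzero(col == col.max())
    pref = int(best[0] if rng is None or best.size == 1 else rng.choice(best))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(test, axis=0)
    others = np.delete(med, pref)
    ref = np.nanmedian(others)
    if np.isnan(med[pref]) or np.isnan(ref):
        return 0.5
    if med[pref] > ref:
        return 1.0
    if med[pref] == ref:
        return 0.5
    return 0.0


def consistency_score(
    table: ResponseTable,
    n_splits: int = 100_000,
    seed: int | np.random.Generator | None = None,
    exact: bool = False,
) -> tuple[float, float]:
    """Split-half consistency of the stimulus preference.

    Random halves of size ``floor(n/2)`` / ``ceil(n/2)``; the preference is
    chosen on the first half (argmax of summed counts, ties broken at
    random) and confirmed on the held-out half when the preferred median
    response exceeds the median of the other stimuli's medians. Exact median
    ties score 0.5, keeping the no-preference null at the 50% chance level.

    Returns ``(proportion, p)`` with a one-sided binomial test of the
    confirmation count against 1/2. With ``exact=True`` every half-split is
    enumerated (small tables only) and the proportion is deterministic.
    """
    n = table.n_iterations
    if n < 4:
        raise InsufficientDataError(f"need >= 4 iterations, got {n}")
    if not exact and n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    m = table.masked()
    h = n // 2

    if exact:
        credits = []
        for train_rows in combinations(range(n), h):
            test_rows = sorted(set(range(n)) - set(train_rows))
            train, test = m[list(train_rows)], m[test_rows]
            col = np.nansum(train, axis=0)
            best = np.flatnonzero(col == col.max())
            # average over tied training preferences instead of randomising
            credit = float(
                np.mean([_credit_for_pref(test, int(b)) for b in best])
            )
            credits.append(credit)
        proportion = float(np.mean(credits))
        return proportion, float("nan")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chunk = max(1, min(n_splits, 20_000))
    total_credit = 0.0
    done = 0
    while done < n_splits:
        b = min(chunk, n_splits - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        train = m[perms[:, :h]]  # (b, h, S)
        test = m[perms[:, h:]]  # (b, n-h, S)
        col = np.nansum(train, axis=1)  # (b, S)
        # random tie-break via an infinitesimal jitter
        jitter = rng.random(col.shape) * 1e-9
        pref = np.argmax(col + jitter, axis=1)  # (b,)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(test, axis=1)  # (b, S)
            med_pref = np.take_along_axis(med, pref[:, None], axis=1)[:, 0]
            med_others = med.copy()
            np.put_along_axis(med_others, pref[:, None], np.nan, axis=1)
            ref = np.nanmedian(med_others, axis=1)
        credit = np.where(med_pref > ref, 1.0, np.where(med_pref == ref, 0.5, 0.0))
        credit = np.where(np.isnan(med_pref) | np.isnan(ref), 0.5, credit)
        total_credit += float(credit.sum())
        done += b
    proportion = total_credit / n_splits
    k = int(round(proportion * n_splits))
    p = float(stats.binomtest(k, n_splits, 0.5, alternative="greater").pvalue)
    return proportion, p


def _credit_for_pref(test: np.ndarray, pref: int) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(test, axis=0)
    others = np.delete(med, pref)
    ref = np.nanmedian(others)
    if np.isnan(med[pref]) or np.isnan(ref):
        return 0.5
    return 1.0 if med[pref] > ref else (0.5 if med[pref] == ref else 0.0)


def classify_tuning(
    table: ResponseTable, consistency_p: float, alpha: float = 0.05
) -> str:
    """*inconsistent* if the split-half test fails; otherwise *strong* when a
    one-way ANOVA of counts on stimulus identity is significant, else *weak*."""
    if not (consistency_p < alpha):
        return "inconsistent"
    m = table.masked()
    groups = [m[:, s][~np.isnan(m[:, s])] for s in range(table.n_stimuli)]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2 or all(np.ptp(g) == 0 for g in groups):
        warnings.warn(f"unit {table.unit_id}: degenerate counts, ANOVA undefined", stacklevel=2)
        return "weak"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(p):
        warnings.warn(f"unit {table.unit_id}: ANOVA undefined, classing weak", stacklevel=2)
        return "weak"
    return "strong" if p < alpha else "weak"


def compute_tuning(
    session: Session,
    unit_id: str,
    window: tuple[float, float] = DEFAULT_RESPONSE_WINDOW,
    n_splits: int = 100_000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> CellTuning:
    """Full preference + reliability + class for one unit."""
    table = build_response_table(session, unit_id, window)
    order = session.sequence_order()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        preferred, preceding, following = identify_preferred(table, order)
        tied = any("tied preference" in str(w.message) for w in caught)
    proportion, p = consistency_score(table, n_splits=n_splits, seed=seed)
    cls = classify_tuning(table, p, alpha=alpha)
    return CellTuning(
        unit_id=unit_id,
        preferred_id=preferred,
        preceding_id=preceding,
        following_id=following,
        consistency=proportion,
        consistency_p=p,
        tuning_class=cls,
        preference_tied=tied,
    )


def population_firing_timecourse(
    session: Session,
    tunings: list[CellTuning],
    span: tuple[float, float] = (-2.5, 3.5),
    bin_s: float = 0.05,
    baseline: tuple[float, float] = (-2.5, -2.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean baseline-corrected firing rate around preferred-stimulus onsets.

    Per cell: a PSTH aligned to every non-probe onset of its preferred
    stimulus over ``span``, minus the mean rate in the ``baseline`` window;
    averaged across cells. Returns ``(bin_centers_s, mean_rate_hz)``.
    """
    included = [tu for tu in tunings if tu.tuning_class != "inconsistent"]
    if not included:
        raise InsufficientDataError("no consistent cells for the population time course")
    edges = np.arange(span[0], span[1] + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    curves = []
    for tu in included:
        t = session.get_unit(tu.unit_id).spike_times_s
        onsets = [
            e.onset_s
            for e in session.events
            if e.stimulus_id == tu.preferred_id and not e.is_probe
        ]
        if not onsets:
            continue
        counts = np.zeros(centers.size)
        for onset in onsets:
            rel = t[(t >= onset + span[0]) & (t < onset + span[1])] - onset
            counts += np.histogram(rel, bins=edges)[0]
        rate = counts / (len(onsets) * bin_s)
        base = rate[(centers >= baseline[0]) & (centers < baseline[1])].mean()
        curves.append(rate - base)
    return centers, np.mean(curves, axis=0)
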