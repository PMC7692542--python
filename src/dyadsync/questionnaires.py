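"""Self-report outcome variables.

Interpersonal attraction is the mean of 8 Likert items (1..7) with scale
reliability reported as Cronbach's alpha. Impression accuracy is the profile
correlation: Pearson r between a participant's 15 self-ratings and the
partner's 15 observer ratings over pairwise-complete items. Affective
valence is the positive-minus-negative emotion-word percentage difference;
the dictionary engine producing the percentages is upstream, but a simple
user-lexicon counter is provided.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import DataError

log = logging.getLogger(__name__)


def attraction_score(items) -> float:
    """Mean of the 8 attraction items; missing items are an error."""
    items = np.asarray(items, dtype=float)
    if items.shape != (8,):
        raise DataError(f"attraction scale requires exactly 8 items, got {items.shape}")
    if np.any(np.isnan(items)):
        raise DataError("missing attraction item")
    if np.any((items < 1) | (items > 7)):
        raise DataError("attraction item outside 1..7")
    return float(items.mean())


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/variance(total)).

    Variances are sample variances (ddof=1) over the n participants.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DataError("alpha requires at least 2 participants and 2 items")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DataError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def profile_correlation(self_items, observer_items, min_items: int = 5) -> float:
    """Pearson r across pairwise-complete personality items; NaN if undefined.

    Returns NaN (a missing value, with the reason logged) when fewer than
    ``min_items`` complete pairs remain or either profile is constant.
    """
    a = np.asarray(self_items, dtype=float)
    b = np.asarray(observer_items, dtype=float)
    if a.shape != b.shape:
        raise DataError("profiles must cover the same item set")
    complete = ~np.isnan(a) & ~np.isnan(b)
    if complete.sum() < min_items:
        log.info("profile correlation missing: only %d complete pairs",
                 int(complete.sum()))
        return np.nan
    a, b = a[complete], b[complete]
    if a.std() == 0 or b.std() == 0:
        log.info("profile correlation missing: constant profile")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def affective_valence(pos_pct: float, neg_pct: float) -> float:
    """Positive minus negative emotion-word percentage."""
    if not (0 <= pos_pct <= 100 and 0 <= neg_pct <= 100):
        raise DataError("emotion-word percentages must lie in [0, 100]")
    return float(pos_pct) - float(neg_pct)


def lexicon_rate(tokens, lexicon) -> float:
    """Percentage of tokens matching a word set (case-insensitive).

    A minimal stand-in counter for workflows where dictionary percentages
    are not supplied directly.
    """
    tokens = list(tokens)
    if not tokens:
        raise DataError("cannot compute a rate over zero tokens")
    lex = {w.lower() for w in lexicon}
    matched = sum(1 for t in tokens if t.lower() in lex)
    return 100.0 * matched / len(tokens)


def outcome_records(questionnaires, min_profile_items: int = 5):
    """Per-participant outcome table rows from questionnaire records.

    Impression accuracy pairs each participant's self profile with the
    *partner's* observer ratings of them; participants are matched by the
    ``_p1``/``_p2`` suffix convention within a dyad.
    """
    import pandas as pd

    by_id = {q.participant_id: q for q in questionnaires}
    rows = []
    for q in questionnaires:
        partner_id = _partner_id(q.participant_id)
        partner = by_id.get(partner_id)
        accuracy = (
            profile_correlation(q.bfi_self, partner.bfi_observer,
                                min_profile_items)
            if partner is not None else np.nan
        )
        rows.append({
            "participant_id": q.participant_id,
            "attraction": attraction_score(q.attraction_items),
            "impression_accuracy": accuracy,
            "affective_valence": affective_valence(q.pos_pct, q.neg_pct),
            "gender": q.gender,
        })
    return pd.DataFrame(rows)


def _partner_id(participant_id: str) -> str:
    if participant_id.endswith("_p1"):
        return participant_id[:-3] + "_p2"
    if participant_id.endswith("_p2"):
        return participant_id[:-3] + "_p1"
    return ""
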