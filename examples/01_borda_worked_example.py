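"""Borda-count aggregation of three signal-detection rankings.

Three methods rank five drug-ADR pairs (A..E); the Borda count of a pair is
the sum of its per-method ranks, and the smallest count wins. Pair D is
ranked first by two methods but last by the third, while B is ranked second
by all three — the consensus-seeking aggregation puts B on top.
"""

import pandas as pd

from pvborda import borda_aggregate, scores_to_ranking


def ranking_from_order(method_id, order):
    scores = pd.Series({code: -float(i) for i, code in enumerate(order)})
    return scores_to_ranking(scores, method_id=method_id)


rankings = [
    ranking_from_order("method1", ["D", "B", "C", "E", "A"]),
    ranking_from_order("method2", ["D", "B", "A", "C", "E"]),
    ranking_from_order("method3", ["A", "B", "C", "E", "D"]),
]

result = borda_aggregate(rankings)
print(result.table)
print(
    "\nB has the smallest Borda count (6 = 2+2+2) and tops the consensus "
    "ranking; D's split vote (1+1+5 = 7) puts it second."
)
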