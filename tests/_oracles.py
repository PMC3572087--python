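"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they validate: counting by brute
force, AUC as the pairwise U statistic, and PROSITE matching by mechanical
translation to regular expressions.
"""

from __future__ import annotations

import re
from itertools import product

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


def kmer_counts(peptide: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(peptide) - k + 1):
        counts[peptide[i : i + k]] = counts.get(peptide[i : i + k], 0) + 1
    return counts


def reversal_classes() -> set[frozenset]:
    """All {triplet, reversed} equivalence classes by exhaustive enumeration."""
    return {
        frozenset({"".join(t), "".join(t)[::-1]})
        for t in product(AA, repeat=3)
    }


def auc_u_statistic(scores, labels) -> float:
    """AUC as the Mann-Whitney pairwise probability with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def metrics_closed_forms(tp, fp, tn, fn) -> dict[str, float]:
    def div(a, b):
        return a / b if b else 0.0

    sen = div(tp, tp + fn)
    spe = div(tn, tn + fp)
    pre = div(tp, tp + fp)
    acc = div(tp + tn, tp + tn + fp + fn)
    f1 = div(2 * pre * sen, pre + sen)
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5
    mcc = div(tp * tn - fp * fn, den)
    return {"sen": sen, "spe": spe, "pre": pre, "acc": acc, "f1": f1, "mcc": mcc}


def prosite_to_regex(pattern_text: str) -> str:
    """Mechanical translation of the dash-separated PROSITE dialect to regex."""
    out = []
    for token in pattern_text.strip().rstrip(".").split("-"):
        token = token.strip()
        m = re.search(r"\((\d+)(?:,(\d+))?\)$", token)
        if m:
            rep = f"{{{m.group(1)},{m.group(2)}}}" if m.group(2) else f"{{{m.group(1)}}}"
            token = token[: m.start()]
        else:
            rep = ""
        if token == "x":
            out.append("." + rep)
        elif token.startswith("[") and token.endswith("]"):
            out.append(token + rep)
        elif token.startswith("{") and token.endswith("}"):
            out.append("[^" + token[1:-1] + "]" + rep)
        else:
            out.append(token + rep)
    return "".join(out)


def regex_match_starts(pattern_text: str, sequence: str) -> list[int]:
    """1-based start positions where the translated regex matches."""
    rx = re.compile(prosite_to_regex(pattern_text))
    return [i + 1 for i in range(len(sequence)) if rx.match(sequence, i)]
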