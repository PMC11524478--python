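"""Evaluation of predicted provenance against ground-truth annotations.

Three complementary tasks, each summarized by a harmonic mean, scored at the
image (panel) level and at the document level:

* content pairing — link precision LP and link recall LR over unordered id
  pairs; CP = 2 LP LR / (LP + LR);
* content grouping — predicted groups (connected components) matched to
  annotated categories by greedy maximum overlap, node precision NP =
  overlap / |predicted group| and node recall NR = overlap / |category|;
  CG = 2 NP NR / (NP + NR);
* content classification — set precision/recall of suspicious items
  (everything appearing in any provenance graph); CC is their harmonic mean.

Harmonic means are defined as 0 when both arguments are 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable

from .errors import ValidationError

Link = frozenset  # unordered id pair


def harmonic_mean(a: float, b: float) -> float:
    return 0.0 if a + b == 0 else 2.0 * a * b / (a + b)


def normalize_links(links: Iterable[tuple[str, str] | frozenset]) -> set[frozenset]:
    out = set()
    for link in links:
        pair = frozenset(link)
        if len(pair) != 2:
            raise ValidationError(f"link {link!r} is not a pair of distinct ids")
        out.add(pair)
    return out


@dataclass
class GroundTruth:
    """Annotated reuse at one level (image or document).

    ``categories`` maps a category label (e.g. a reuse group like "TW14") to
    its member ids. Links are every unordered cross-member pair within a
    category; the suspicious set is the union of all grouped ids.
    """

    categories: dict[str, set[str]]
    corpus_ids: set[str] | None = None  # all ids at this level, if known

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.categories.items():
            dup = seen & set(members)
            if dup:
                raise ValidationError(
                    f"ids {sorted(dup)} appear in more than one category"
                )
            seen |= set(members)

    @property
    def links(self) -> set[frozenset]:
        out = set()
        for members in self.categories.values():
            members = sorted(members)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    out.add(frozenset((a, b)))
        return out

    @property
    def suspicious(self) -> set[str]:
        return set().union(*self.categories.values()) if self.categories else set()


@dataclass
class MetricsReport:
    LP: float
    LR: float
    CP: float
    NP: float
    NR: float
    CG: float
    precision: float
    recall: float
    CC: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("LP", "LR", "CP", "NP", "NR", "CG", "precision", "recall", "CC")}


def _check_ids(ids: Iterable[str], truth: GroundTruth, what: str) -> None:
    if truth.corpus_ids is None:
        return
    unknown = set(ids) - truth.corpus_ids
    if unknown:
        raise ValidationError(f"{what} contains ids absent from the corpus: {sorted(unknown)[:5]}")


def content_pairing(
    predicted_links: Iterable[tuple[str, str] | frozenset], truth: GroundTruth
) -> tuple[float, float, float]:
    """(LP, LR, CP) of predicted unordered links against annotated ones.

    Both-empty sides score 1.0 (nothing to find, nothing falsely found).
    """
    predicted = normalize_links(predicted_links)
    _check_ids((i for link in predicted for i in link), truth, "predicted links")
    annotated = truth.links
    correct = len(predicted & annotated)
    LP = correct / len(predicted) if predicted else (1.0 if not annotated else 0.0)
    LR = correct / len(annotated) if annotated else (1.0 if not predicted else 0.0)
    return LP, LR, harmonic_mean(LP, LR)


def content_grouping(
    predicted_groups: Iterable[Collection[str]], truth: GroundTruth
) -> tuple[float, float, float]:
    """(NP, NR, CG) via greedy maximum-overlap matching of groups to categories.

    Groups and categories are paired greedily, largest overlap first (ties:
    smaller predicted-group index, then category label), each used at most
    once. Unmatched predicted groups contribute zero-overlap precision terms;
    unmatched categories contribute zero-overlap recall terms. NP and NR are
    averaged over their respective term lists.
    """
    groups = [set(g) for g in predicted_groups]
    for i, g in enumerate(groups):
        for h in groups[i + 1 :]:
            if g & h:
                raise ValidationError("predicted groups overlap")
    _check_ids((i for g in groups for i in g), truth, "predicted groups")

    cats = {label: set(m) for label, m in truth.categories.items()}
    overlaps = sorted(
        (
            (-len(g & members), gi, label)
            for gi, g in enumerate(groups)
            for label, members in cats.items()
            if g & members
        ),
    )
    used_groups: set[int] = set()
    used_cats: set[str] = set()
    np_terms: list[float] = []
    nr_terms: list[float] = []
    for neg_overlap, gi, label in overlaps:
        if gi in used_groups or label in used_cats:
            continue
        used_groups.add(gi)
        used_cats.add(label)
        overlap = -neg_overlap
        np_terms.append(overlap / len(groups[gi]))
        nr_terms.append(overlap / len(cats[label]))
    np_terms += [0.0] * (len(groups) - len(used_groups))
    nr_terms += [0.0] * (len(cats) - len(used_cats))

    if not np_terms and not nr_terms:  # nothing predicted, nothing annotated
        return 1.0, 1.0, 1.0
    NP = sum(np_terms) / len(np_terms) if np_terms else 0.0
    NR = sum(nr_terms) / len(nr_terms) if nr_terms else 0.0
    return NP, NR, harmonic_mean(NP, NR)


def content_classification(
    predicted_suspicious: Iterable[str], truth: GroundTruth
) -> tuple[float, float, float]:
    """(precision, recall, CC) of the predicted suspicious-item set."""
    predicted = set(predicted_suspicious)
    _check_ids(predicted, truth, "predicted suspicious set")
    annotated = truth.suspicious
    tp = len(predicted & annotated)
    precision = tp / len(predicted) if predicted else (1.0 if not annotated else 0.0)
    recall = tp / len(annotated) if annotated else (1.0 if not predicted else 0.0)
    return precision, recall, harmonic_mean(precision, recall)


def evaluate(
    predicted_links: Iterable[tuple[str, str] | frozenset],
    predicted_groups: Iterable[Collection[str]],
    predicted_suspicious: Iterable[str],
    truth: GroundTruth,
) -> MetricsReport:
    """Full report over the three tasks at one level."""
    LP, LR, CP = content_pairing(predicted_links, truth)
    NP, NR, CG = content_grouping(predicted_groups, truth)
    precision, recall, CC = content_classification(predicted_suspicious, truth)
    return MetricsReport(LP, LR, CP, NP, NR, CG, precision, recall, CC)
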