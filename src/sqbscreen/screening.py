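"""Similarity searching, recall evaluation, and result tables.

The screening protocol ranks a compound library against one reference
structure at a time, reads off the percentage of each activity class's
actives retrieved in the top 1% / 5% of the ranking (recall), averages over
a fixed panel of randomly drawn references per class, and summarises a
class x method recall table by its column means and per-row best-method
("shaded cell") counts.

:class:`SimilarityScreener` is the workhorse: a scikit-learn style
estimator whose ``fit`` ingests the library (computing corpus statistics
and dense score caches) and whose ``rank`` produces a full ranked list for
one reference.  The five supported methods are the continuous Tanimoto
benchmark (``tan``) on raw counts and the quantum projection probability on
the four embeddings (``sqb-real``, ``sqb-tech1``, ``sqb-tech2``,
``sqb-okapi``).  Scoring is vectorised with numpy; the per-compound
embedding route in :mod:`sqbscreen.weighting` serves as its reference
implementation in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fingerprints import (
    ActivityLabels,
    CorpusStats,
    CountFingerprint,
    compute_corpus_stats,
)
from .weighting import Technique

__all__ = [
    "METHODS",
    "METHOD_DISPLAY_NAMES",
    "RankedList",
    "ScreeningResult",
    "SimilarityScreener",
    "rank_library",
    "recall_at",
    "evaluate",
    "summarize_table",
]

#: Canonical method tokens in the column order used throughout.
METHODS = ("sqb-tech1", "sqb-tech2", "sqb-okapi", "sqb-real", "tan")

#: Human-readable column labels for result tables.
METHOD_DISPLAY_NAMES = {
    "sqb-tech1": "SQB(C./T1)",
    "sqb-tech2": "SQB(C./T2)",
    "sqb-okapi": "SQB(C./T3)",
    "sqb-real": "SQB(R.)",
    "tan": "TAN",
}


def normalize_method(token: str) -> str:
    tok = str(token).lower().strip()
    aliases = {
        "tan": "tan",
        "tanimoto": "tan",
        "real": "sqb-real",
        "tech1": "sqb-tech1",
        "tech2": "sqb-tech2",
        "okapi": "sqb-okapi",
        "tech3": "sqb-okapi",
    }
    tok = aliases.get(tok, tok)
    if tok not in METHODS:
        raise ValueError(f"unknown similarity method {token!r}; expected one of {METHODS}")
    return tok


@dataclass(frozen=True)
class RankedList:
    """Ranked library for one reference: ``(compound_id, score)`` descending.

    Ties are broken by ascending compound id so rankings are
    machine-independent; the reference itself is excluded.
    """

    reference_id: str
    entries: tuple

    def ids(self) -> list[str]:
        return [cid for cid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ScreeningResult:
    """Recall table for one cutoff fraction, plus its aggregates.

    ``table`` is a class x method matrix of mean recall percentages;
    ``mean_row`` its column means; ``shaded_cells`` counts, per method, the
    rows where that method attains the row maximum (ties all counted);
    ``references`` records the per-class reference panel the run used.
    """

    cutoff_fraction: float
    table: pd.DataFrame
    mean_row: pd.Series
    shaded_cells: pd.Series
    references: Mapping[str, tuple] = field(default_factory=dict)


class SimilarityScreener(BaseEstimator):
    """Rank a fingerprint library against reference structures.

    Parameters
    ----------
    method:
        ``'tan'`` (continuous Tanimoto on raw counts) or one of the
        projection-probability variants ``'sqb-real'``, ``'sqb-tech1'``,
        ``'sqb-tech2'``, ``'sqb-okapi'``.
    size_mode:
        Compound-length convention for the weighting ('total' or 'distinct').
    weighted_tan:
        If True, feed the Tanimoto benchmark the modulus of the method-free
        global-weight embedding instead of raw counts.  Raw counts are the
        standard benchmark usage and the default.

    Attributes
    ----------
    stats_ : CorpusStats
        Corpus statistics of the fitted library.
    library_ids_ : list of str
    """

    def __init__(
        self,
        method: str = "sqb-okapi",
        size_mode: str = "total",
        weighted_tan: bool = False,
    ):
        self.method = method
        self.size_mode = size_mode
        self.weighted_tan = weighted_tan

    # -- fitting ------------------------------------------------------------

    def fit(self, X: Sequence[CountFingerprint], y=None) -> "SimilarityScreener":
        normalize_method(self.method)  # validate early
        library = list(X)
        self.stats_ = compute_corpus_stats(library, size_mode=self.size_mode)
        self.library_ids_ = [fp.compound_id for fp in library]
        self._by_id = {fp.compound_id: fp for fp in library}

        frag_ids = sorted(self.stats_.doc_freq)
        self._frag_index = {f: i for i, f in enumerate(frag_ids)}
        n, nf = len(library), len(frag_ids)
        counts = np.zeros((n, nf))
        for row, fp in enumerate(library):
            for frag, cnt in fp.counts.items():
                counts[row, self._frag_index[frag]] = cnt
        self._counts = counts
        self._ids_arr = np.array(self.library_ids_)

        m = self.stats_.num_compounds
        cf = np.array([self.stats_.doc_freq[f] for f in frag_ids], dtype=float)
        self._global_w = np.log((m + 0.5) / cf) / np.log(m + 1)
        sizes = np.array(
            [self.stats_.sizes[cid] for cid in self.library_ids_], dtype=float
        )
        self._sizes = sizes
        # local Okapi denominator is per-compound, reference-independent
        self._tech1 = counts / (
            counts + 0.5 + 1.5 * (sizes / self.stats_.avg_size)[:, None]
        )
        self._tech1[counts == 0] = 0.0
        self._sq_norms = (counts**2).sum(axis=1)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "stats_"):
            raise ValueError("SimilarityScreener is not fitted; call fit first")

    # -- scoring ------------------------------------------------------------

    def _reference_vector(self, reference: CountFingerprint) -> np.ndarray:
        vec = np.zeros(len(self._frag_index))
        for frag, cnt in reference.counts.items():
            idx = self._frag_index.get(frag)
            if idx is None:
                raise ValueError(
                    f"fragment {frag} of reference {reference.compound_id!r} is "
                    "absent from the fitted library"
                )
            vec[idx] = cnt
        return vec

    def _score_all(self, reference: CountFingerprint) -> np.ndarray:
        """Similarity of every fitted library compound to the reference."""
        method = normalize_method(self.method)
        r_counts = self._reference_vector(reference)
        counts = self._counts

        if method == "tan":
            lib = counts
            ref = r_counts
            if self.weighted_tan:
                mask = counts > 0
                lib = mask * self._global_w[None, :]
                ref = (r_counts > 0) * self._global_w
            dot = lib @ ref
            denom = (lib**2).sum(axis=1) + (ref**2).sum() - dot
            with np.errstate(invalid="ignore", divide="ignore"):
                scores = np.where(denom > 0, dot / denom, 0.0)
            return scores

        technique = Technique.from_token(method)
        mask = counts > 0
        re_part = mask * self._global_w[None, :]

        ref_size = float(
            self.stats_.sizes.get(
                reference.compound_id, reference.size(self.size_mode)
            )
        )
        ref_mask = r_counts > 0
        ref_tech1 = np.where(
            ref_mask,
            r_counts / (r_counts + 0.5 + 1.5 * ref_size / self.stats_.avg_size),
            0.0,
        )
        if technique is Technique.REAL:
            im_lib = np.zeros_like(counts)
            im_ref = np.zeros_like(r_counts)
        elif technique is Technique.TECH1:
            im_lib = self._tech1
            im_ref = ref_tech1
        elif technique is Technique.TECH2:
            im_lib = self._tech1 * self._global_w[None, :]
            im_ref = ref_tech1 * self._global_w
        else:  # TECH3_OKAPI: count-agreement factor couples library to reference
            with np.errstate(invalid="ignore", divide="ignore"):
                agree = np.minimum(counts, r_counts) / np.maximum(counts, r_counts)
            agree = np.nan_to_num(agree)
            im_lib = self._tech1 * self._global_w[None, :] * agree
            # the reference against itself has factor 1 on its support
            im_ref = ref_tech1 * self._global_w

        ref_vec = ref_mask * self._global_w + 1j * im_ref
        lib_vecs = re_part + 1j * im_lib
        inner = lib_vecs @ ref_vec.conj()
        lib_norm_sq = (np.abs(lib_vecs) ** 2).sum(axis=1)
        ref_norm_sq = float((np.abs(ref_vec) ** 2).sum())
        denom = lib_norm_sq * ref_norm_sq
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(denom > 0, (np.abs(inner) ** 2) / denom, 0.0)
        return scores

    def rank(self, reference: "CountFingerprint | str") -> RankedList:
        """Rank every fitted library compound (except the reference) descending.

        ``reference`` may be a fingerprint object or the id of a library
        member.  Equal scores are ordered by ascending compound id.
        """
        self._check_fitted()
        if isinstance(reference, str):
            if reference not in self._by_id:
                raise KeyError(f"reference id {reference!r} not in fitted library")
            reference = self._by_id[reference]
        scores = self._score_all(reference)
        keep = self._ids_arr != reference.compound_id
        ids = self._ids_arr[keep]
        scores = scores[keep]
        order = np.lexsort((ids, -scores))
        entries = tuple(
            (str(ids[i]), float(scores[i])) for i in order
        )
        return RankedList(reference_id=reference.compound_id, entries=entries)


def rank_library(
    reference: CountFingerprint,
    library: Sequence[CountFingerprint],
    stats: Optional[CorpusStats] = None,
    method: str = "tan",
    size_mode: str = "total",
) -> RankedList:
    """One-shot ranking of ``library`` against ``reference``.

    Thin wrapper over :class:`SimilarityScreener`; ``stats``, if given, must
    match the library and merely spares revalidation.
    """
    screener = SimilarityScreener(method=method, size_mode=size_mode).fit(library)
    return screener.rank(reference)


# ---------------------------------------------------------------------------
# recall and aggregation
# ---------------------------------------------------------------------------

def recall_at(ranked: RankedList, actives: Iterable[str], fraction: float) -> float:
    """Percentage of actives retrieved in the top ``fraction`` of the ranking.

    The cutoff is ``round(fraction * N)`` positions (half away from zero),
    never fewer than 1.  ``actives`` must exclude the reference (which is
    not in the ranked list).
    """
    if not 0 < fraction < 1:
        raise ValueError(f"cutoff fraction must lie in (0, 1), got {fraction}")
    active_set = set(actives)
    if not active_set:
        raise ValueError("actives set is empty")
    n_list = len(ranked)
    cutoff = max(1, math.floor(fraction * n_list + 0.5))
    top = {cid for cid, _ in ranked.entries[:cutoff]}
    return 100.0 * len(top & active_set) / len(active_set)


def summarize_table(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Column means and per-row best-method counts of a recall table.

    Rows are activity classes, columns methods, values recall percentages.
    Every row's maximal cell is "shaded"; ties shade every tied method.
    """
    if table.empty:
        raise ValueError("recall table is empty")
    if table.isna().any().any():
        missing = [
            (str(r), str(c))
            for r, c in zip(*np.where(table.isna().to_numpy()))
        ]
        raise ValueError(f"recall table has missing cells at {missing[:5]}")
    values = table.to_numpy(dtype=float)
    if values.min() < 0 or values.max() > 100:
        raise ValueError("recall values must lie in [0, 100]")
    mean_row = table.mean(axis=0)
    row_max = values.max(axis=1, keepdims=True)
    shaded = pd.Series(
        (values == row_max).sum(axis=0), index=table.columns, dtype=int
    )
    return mean_row, shaded


def evaluate(
    library: Sequence[CountFingerprint],
    labels: ActivityLabels,
    references_per_class: int = 10,
    methods: Sequence[str] = METHODS,
    fractions: Sequence[float] = (0.01, 0.05),
    seed: Optional[int] = None,
    size_mode: str = "total",
) -> list[ScreeningResult]:
    """Full screening benchmark: one :class:`ScreeningResult` per cutoff.

    For every activity class, ``references_per_class`` references are drawn
    once with a seeded generator and the *same* panel is reused for every
    method ("unified" references).  Per-class recall is the mean over the
    single-reference searches; the reference is excluded from both the
    ranked candidates and the recall denominator.
    """
    library = list(library)
    methods = [normalize_method(mtd) for mtd in methods]
    labels.validate_against(fp.compound_id for fp in library)
    rng = np.random.default_rng(seed)

    class_ids = labels.class_ids()
    references: dict[str, list[str]] = {}
    for cid in class_ids:
        members = sorted(labels.actives(cid))
        if len(members) <= references_per_class:
            raise ValueError(
                f"activity class {cid!r} has {len(members)} members; needs more "
                f"than references_per_class={references_per_class}"
            )
        references[cid] = list(
            rng.choice(members, size=references_per_class, replace=False)
        )

    tables = {
        frac: pd.DataFrame(
            index=pd.Index(class_ids, name="activity_class"),
            columns=list(methods),
            dtype=float,
        )
        for frac in fractions
    }
    for method in methods:
        screener = SimilarityScreener(method=method, size_mode=size_mode).fit(library)
        for cid in class_ids:
            members = labels.actives(cid)
            per_ref: dict[float, list[float]] = {frac: [] for frac in fractions}
            for ref_id in references[cid]:
                ranked = screener.rank(ref_id)
                actives = members - {ref_id}
                for frac in fractions:
                    per_ref[frac].append(recall_at(ranked, actives, frac))
            for frac in fractions:
                tables[frac].loc[cid, method] = float(np.mean(per_ref[frac]))

    results = []
    for frac in fractions:
        mean_row, shaded = summarize_table(tables[frac])
        results.append(
            ScreeningResult(
                cutoff_fraction=float(frac),
                table=tables[frac],
                mean_row=mean_row,
                shaded_cells=shaded,
                references={cid: tuple(refs) for cid, refs in references.items()},
            )
        )
    return results
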