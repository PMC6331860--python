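"""Fragment weighting and complex-valued molecular embeddings.

Each fragment of a compound is embedded as a complex number whose real part
is an inverse-collection-frequency ("global") weight and whose imaginary
part is one of three increasingly informed technique weights:

* ``TECH1`` — local Okapi-style term-frequency weight only, a function of
  the fragment's count in the compound and the compound's length.
* ``TECH2`` — the local weight multiplied by the global weight.
* ``TECH3_OKAPI`` — the full modified Okapi weight: local x global x a
  reference-coupling factor ``min(ff_c, ff_r) / max(ff_c, ff_r)`` that
  rewards fragments whose counts agree between compound and reference.
* ``REAL`` — the real special case: imaginary part identically zero, so the
  state lives in a real Hilbert space.

All four formulas are non-negative on their domains; the local weight is
strictly below 1 and increases with the fragment count, and the global
weight strictly decreases with collection frequency (rare fragments are
informative, ubiquitous ones nearly vanish).

:class:`QuantumEmbedder` packages the embedding as a scikit-learn style
transformer: ``fit`` learns the corpus statistics, ``transform`` maps
fingerprints to :class:`ComplexVector` states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .fingerprints import CorpusStats, CountFingerprint, compute_corpus_stats

__all__ = [
    "Technique",
    "WeightScheme",
    "ComplexVector",
    "global_weight",
    "tech1_weight",
    "tech2_weight",
    "tech3_okapi_weight",
    "embed_compound",
    "QuantumEmbedder",
]


class Technique(str, Enum):
    """Imaginary-part weighting technique of the complex embedding."""

    TECH1 = "tech1"
    TECH2 = "tech2"
    TECH3_OKAPI = "okapi"
    REAL = "real"

    @classmethod
    def from_token(cls, token: "Technique | str") -> "Technique":
        if isinstance(token, Technique):
            return token
        tok = str(token).lower().strip()
        tok = tok.removeprefix("sqb-")
        for t in cls:
            if t.value == tok:
                return t
        raise ValueError(
            f"unknown weighting technique {token!r}; "
            f"expected one of {[t.value for t in cls]}"
        )


@dataclass(frozen=True)
class WeightScheme:
    """Embedding configuration: technique plus compound-size convention."""

    technique: Technique = Technique.TECH3_OKAPI
    size_mode: str = "total"

    def __post_init__(self) -> None:
        object.__setattr__(self, "technique", Technique.from_token(self.technique))
        if self.size_mode not in ("total", "distinct"):
            raise ValueError(f"unknown size mode {self.size_mode!r}")


@dataclass(frozen=True)
class ComplexVector:
    """Sparse complex embedding of one compound: ``fragment -> re + im*i``.

    Entries exist only for fragments present in the underlying compound;
    both components are non-negative by construction.
    """

    compound_id: str
    entries: Mapping[int, complex] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entries", {int(f): complex(v) for f, v in self.entries.items()}
        )

    def norm_sq(self) -> float:
        return sum(abs(v) ** 2 for v in self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# weight formulas
# ---------------------------------------------------------------------------

def global_weight(cf_i: int, m: int) -> float:
    """Inverse-collection-frequency weight ``log((m + 0.5) / cf_i) / log(m + 1)``.

    ``cf_i`` is the number of compounds containing the fragment, ``m`` the
    total number of compounds.  Strictly decreasing in ``cf_i``; positive for
    every attainable ``cf_i <= m``.  The ratio of logarithms is base
    invariant; natural logs are used.
    """
    if m < 1:
        raise ValueError(f"collection size m must be >= 1, got {m}")
    if cf_i < 1 or cf_i > m:
        raise ValueError(f"collection frequency must satisfy 1 <= cf <= m, got cf={cf_i}, m={m}")
    return math.log((m + 0.5) / cf_i) / math.log(m + 1)


def tech1_weight(ff_ij: int, c_j: float, c_avg: float) -> float:
    """Local term-frequency weight ``ff / (ff + 0.5 + 1.5 |c_j| / |c_avg|)``.

    Saturating in the fragment count ``ff_ij`` and damped by the compound's
    length ``|c_j|`` relative to the collection average ``|c_avg|``; always
    in ``[0, 1)`` and zero when the fragment is absent.
    """
    if c_avg <= 0:
        raise ValueError(f"average compound size must be positive, got {c_avg}")
    if ff_ij < 0 or c_j < 0:
        raise ValueError("fragment count and compound size must be non-negative")
    if ff_ij == 0:
        return 0.0
    return ff_ij / (ff_ij + 0.5 + 1.5 * c_j / c_avg)


def tech2_weight(ff_ij: int, c_j: float, c_avg: float, cf_i: int, m: int) -> float:
    """Local x global weight: ``tech1 * global``."""
    return tech1_weight(ff_ij, c_j, c_avg) * global_weight(cf_i, m)


def tech3_okapi_weight(
    ff_ij: int, ff_ir: int, c_j: float, c_avg: float, cf_i: int, m: int
) -> float:
    """Modified Okapi weight: ``tech2 * min(ff_c, ff_r) / max(ff_c, ff_r)``.

    The extra factor couples the compound to the reference structure:
    it is 1 when the counts agree, shrinks as they diverge, and is 0 when
    the fragment is absent from either (0/0 contributes nothing).
    """
    if ff_ij < 0 or ff_ir < 0:
        raise ValueError("fragment counts must be non-negative")
    hi = max(ff_ij, ff_ir)
    if hi == 0:
        return 0.0
    factor = min(ff_ij, ff_ir) / hi
    return tech2_weight(ff_ij, c_j, c_avg, cf_i, m) * factor


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def _compound_size(
    fp: CountFingerprint, stats: CorpusStats, size_mode: str
) -> float:
    size = stats.sizes.get(fp.compound_id)
    if size is None:
        size = fp.size(size_mode)
    return float(size)


def embed_compound(
    fp: CountFingerprint,
    stats: CorpusStats,
    scheme: WeightScheme,
    reference: Optional[CountFingerprint] = None,
) -> ComplexVector:
    """Embed one compound as a complex state vector.

    For every fragment present in ``fp`` the real component is the global
    weight of that fragment in the collection and the imaginary component is
    the scheme's technique weight (identically zero for ``REAL``).  The
    Okapi technique needs the ``reference`` fingerprint for its
    count-agreement factor; embedding the reference against itself gives
    factor 1 on its whole support.
    """
    tech = scheme.technique
    if tech is Technique.TECH3_OKAPI and reference is None:
        raise ValueError("the Okapi technique requires a reference fingerprint")
    m = stats.num_compounds
    c_j = _compound_size(fp, stats, scheme.size_mode)
    entries: dict[int, complex] = {}
    for frag, ff in fp.counts.items():
        cf = stats.doc_freq.get(frag)
        if cf is None:
            raise ValueError(
                f"fragment {frag} of compound {fp.compound_id!r} is absent from "
                "the corpus statistics; recompute the statistics over a library "
                "containing this compound"
            )
        re = global_weight(cf, m)
        if tech is Technique.REAL:
            im = 0.0
        elif tech is Technique.TECH1:
            im = tech1_weight(ff, c_j, stats.avg_size)
        elif tech is Technique.TECH2:
            im = tech2_weight(ff, c_j, stats.avg_size, cf, m)
        else:  # TECH3_OKAPI
            ff_r = reference.counts.get(frag, 0)
            im = tech3_okapi_weight(ff, ff_r, c_j, stats.avg_size, cf, m)
        entries[frag] = complex(re, im)
    return ComplexVector(fp.compound_id, entries)


class QuantumEmbedder(BaseEstimator, TransformerMixin):
    """Corpus-aware transformer from count fingerprints to complex states.

    Parameters
    ----------
    technique:
        Weighting technique token: ``'tech1'``, ``'tech2'``, ``'okapi'`` or
        ``'real'``.
    size_mode:
        Compound-length convention for the local weight: ``'total'`` (sum of
        counts, the Okapi document-length reading, default) or
        ``'distinct'`` (number of distinct fragments).

    Attributes
    ----------
    stats_ : CorpusStats
        Collection statistics learned by :meth:`fit`.
    num_compounds_ : int
    avg_size_ : float
    """

    def __init__(self, technique: str = "okapi", size_mode: str = "total"):
        self.technique = technique
        self.size_mode = size_mode

    def _scheme(self) -> WeightScheme:
        return WeightScheme(Technique.from_token(self.technique), self.size_mode)

    def fit(self, X: Sequence[CountFingerprint], y=None) -> "QuantumEmbedder":
        self._scheme()  # validate parameters early
        self.stats_ = compute_corpus_stats(X, size_mode=self.size_mode)
        self.num_compounds_ = self.stats_.num_compounds
        self.avg_size_ = self.stats_.avg_size
        return self

    def transform(
        self,
        X: Sequence[CountFingerprint],
        reference: Optional[CountFingerprint] = None,
    ) -> list[ComplexVector]:
        if not hasattr(self, "stats_"):
            raise ValueError("QuantumEmbedder is not fitted; call fit first")
        scheme = self._scheme()
        return [embed_compound(fp, self.stats_, scheme, reference) for fp in X]
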