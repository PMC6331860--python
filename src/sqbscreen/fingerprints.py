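"""Sparse count fingerprints, file formats, and corpus-level statistics.

A molecule is represented by a sparse map ``fragment_id -> count`` — the
count-valued sibling of a folded circular fingerprint (an ECFC_4-style
vector).  Fragment identifiers are arbitrary non-negative integers; folding
to a fixed length is upstream preprocessing and no maximum is imposed here.

The corpus statistics collected by :func:`compute_corpus_stats` are the
collection-frequency quantities the Okapi-style weighting functions need:
the number of compounds *m*, the per-fragment document frequency ``cf_i``
(number of compounds containing fragment *i*), per-compound sizes ``|c_j|``
and their mean ``|c_avg|``.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .qsim import tanimoto_continuous

__all__ = [
    "CountFingerprint",
    "CorpusStats",
    "ActivityLabels",
    "FingerprintParseError",
    "load_fingerprints",
    "write_fingerprints",
    "load_activity_labels",
    "write_activity_labels",
    "compute_corpus_stats",
    "mean_pairwise_similarity",
]


class FingerprintParseError(ValueError):
    """Malformed fingerprint or label file; message names the offending line."""


@dataclass(frozen=True)
class CountFingerprint:
    """One compound's sparse fragment-count vector.

    Parameters
    ----------
    compound_id:
        Opaque identifier, unique within a library.
    counts:
        Mapping ``fragment_id -> occurrence count``.  Zero counts are absent,
        never stored; every stored count must be a positive integer.
    """

    compound_id: str
    counts: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for frag, cnt in self.counts.items():
            if not isinstance(frag, (int,)) or isinstance(frag, bool) or frag < 0:
                raise ValueError(
                    f"fragment id must be a non-negative integer, got {frag!r} "
                    f"in compound {self.compound_id!r}"
                )
            if not isinstance(cnt, int) or isinstance(cnt, bool) or cnt < 1:
                raise ValueError(
                    f"stored count must be a positive integer, got {cnt!r} for "
                    f"fragment {frag} in compound {self.compound_id!r}"
                )
        # freeze the mapping so the dataclass is safely hashable by id
        object.__setattr__(self, "counts", dict(self.counts))

    def size(self, mode: str = "total") -> int:
        """Compound size ``|c_j|``: total occurrences or distinct fragments."""
        if mode == "total":
            return sum(self.counts.values())
        if mode == "distinct":
            return len(self.counts)
        raise ValueError(f"unknown size mode {mode!r}")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class CorpusStats:
    """Collection statistics feeding the fragment weighting functions.

    ``doc_freq[f]`` is the number of compounds containing fragment ``f``
    (``1 <= cf_i <= m`` for every fragment that occurs); ``sizes`` maps each
    compound to ``|c_j|`` under the chosen ``size_mode``; ``avg_size`` is the
    arithmetic mean of the sizes over all ``num_compounds`` compounds.
    """

    num_compounds: int
    doc_freq: Mapping[int, int]
    sizes: Mapping[str, int]
    avg_size: float
    size_mode: str = "total"


@dataclass(frozen=True)
class ActivityLabels:
    """Activity-class membership: ``class_id -> set of active compound ids``.

    Library compounds not listed in any class are decoys/presumed inactives.
    Classes may overlap if the input says so.
    """

    classes: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "classes",
            {str(k): frozenset(v) for k, v in self.classes.items()},
        )

    def actives(self, class_id: str) -> frozenset:
        return self.classes[class_id]

    def class_ids(self) -> list[str]:
        return sorted(self.classes)

    def validate_against(self, library_ids: Iterable[str]) -> None:
        known = set(library_ids)
        for cid, members in self.classes.items():
            missing = members - known
            if missing:
                raise ValueError(
                    f"activity class {cid!r} lists compounds absent from the "
                    f"library: {sorted(missing)[:5]}"
                )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def _parse_sparse_line(line: str, lineno: int) -> CountFingerprint:
    fields = line.rstrip("\n").split("\t")
    compound_id = fields[0].strip()
    if not compound_id:
        raise FingerprintParseError(f"line {lineno}: empty compound id")
    counts: dict[int, int] = {}
    for tok in fields[1:]:
        tok = tok.strip()
        if not tok:
            continue
        frag_s, sep, cnt_s = tok.partition(":")
        if not sep:
            raise FingerprintParseError(
                f"line {lineno}: expected 'fragment:count', got {tok!r}"
            )
        try:
            frag = int(frag_s)
            cnt = int(cnt_s)
        except ValueError as exc:
            raise FingerprintParseError(
                f"line {lineno}: non-integer fragment or count in {tok!r}"
            ) from exc
        if frag < 0:
            raise FingerprintParseError(
                f"line {lineno}: negative fragment id {frag}"
            )
        if cnt <= 0:
            raise FingerprintParseError(
                f"line {lineno}: count must be positive, got {cnt} for fragment {frag}"
            )
        if frag in counts:
            # duplicate keys are never silently summed
            raise FingerprintParseError(
                f"line {lineno}: duplicate fragment id {frag} in compound "
                f"{compound_id!r}"
            )
        counts[frag] = cnt
    return CountFingerprint(compound_id, counts)


def load_fingerprints(path, format: str = "sparse") -> list[CountFingerprint]:
    """Read a fingerprint library from disk.

    ``format='sparse'`` is the primary tab-separated dialect, one compound
    per line: ``compound_id<TAB>frag:count<TAB>frag:count...``; lines
    starting with ``#`` and blank lines are ignored.  ``format='dense'`` is
    a CSV with header ``compound_id,f0,f1,...`` whose zero entries are
    dropped on load.  Duplicate compound ids are rejected in both dialects.
    """
    path = Path(path)
    if format == "sparse":
        fps: list[CountFingerprint] = []
        seen: set[str] = set()
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fp = _parse_sparse_line(line, lineno)
                if fp.compound_id in seen:
                    raise FingerprintParseError(
                        f"line {lineno}: duplicate compound id {fp.compound_id!r}"
                    )
                seen.add(fp.compound_id)
                fps.append(fp)
        return fps
    if format == "dense":
        return _load_dense_csv(path)
    raise ValueError(f"unknown fingerprint format {format!r}")


def _load_dense_csv(path: Path) -> list[CountFingerprint]:
    fps: list[CountFingerprint] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return []
        if not header or header[0] != "compound_id":
            raise FingerprintParseError(
                "line 1: dense CSV must start with a 'compound_id' header column"
            )
        try:
            frag_ids = [int(h.lstrip("f")) for h in header[1:]]
        except ValueError as exc:
            raise FingerprintParseError(
                f"line 1: fragment columns must be named f<integer>: {header[1:]}"
            ) from exc
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            compound_id = row[0].strip()
            if compound_id in seen:
                raise FingerprintParseError(
                    f"line {lineno}: duplicate compound id {compound_id!r}"
                )
            seen.add(compound_id)
            if len(row) != len(header):
                raise FingerprintParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            counts: dict[int, int] = {}
            for frag, cell in zip(frag_ids, row[1:]):
                try:
                    val = int(cell)
                except ValueError as exc:
                    raise FingerprintParseError(
                        f"line {lineno}: non-integer count {cell!r}"
                    ) from exc
                if val < 0:
                    raise FingerprintParseError(
                        f"line {lineno}: negative count {val} for fragment {frag}"
                    )
                if val:
                    counts[frag] = val
            fps.append(CountFingerprint(compound_id, counts))
    return fps


def write_fingerprints(fps: Iterable[CountFingerprint], path) -> None:
    """Write a library in the sparse tab-separated dialect (round-trip safe)."""
    path = Path(path)
    with path.open("w") as fh:
        for fp in fps:
            toks = [fp.compound_id] + [
                f"{frag}:{fp.counts[frag]}" for frag in sorted(fp.counts)
            ]
            fh.write("\t".join(toks) + "\n")


def load_activity_labels(path) -> ActivityLabels:
    """Read activity-class membership from a ``class_id,compound_id`` CSV."""
    path = Path(path)
    classes: dict[str, set] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] == [
                "class_id",
                "compound_id",
            ]:
                continue
            if len(row) < 2:
                raise FingerprintParseError(
                    f"line {lineno}: expected 'class_id,compound_id'"
                )
            classes.setdefault(row[0].strip(), set()).add(row[1].strip())
    return ActivityLabels(classes)


def write_activity_labels(labels: ActivityLabels, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class_id", "compound_id"])
        for cid in sorted(labels.classes):
            for compound in sorted(labels.classes[cid]):
                writer.writerow([cid, compound])


# ---------------------------------------------------------------------------
# corpus statistics
# ---------------------------------------------------------------------------

def compute_corpus_stats(
    library: Sequence[CountFingerprint], size_mode: str = "total"
) -> CorpusStats:
    """Collection statistics over a fingerprint library.

    ``size_mode='total'`` measures ``|c_j|`` as the sum of fragment counts
    (the document-length convention of Okapi weighting); ``'distinct'``
    counts distinct fragments instead.
    """
    library = list(library)
    if not library:
        raise ValueError("cannot compute corpus statistics of an empty library")
    ids = [fp.compound_id for fp in library]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in library")
    doc_freq: dict[int, int] = {}
    sizes: dict[str, int] = {}
    for fp in library:
        sizes[fp.compound_id] = fp.size(size_mode)
        for frag in fp.counts:
            doc_freq[frag] = doc_freq.get(frag, 0) + 1
    m = len(library)
    avg_size = sum(sizes.values()) / m
    return CorpusStats(
        num_compounds=m,
        doc_freq=doc_freq,
        sizes=sizes,
        avg_size=avg_size,
        size_mode=size_mode,
    )


def mean_pairwise_similarity(class_members: Sequence[CountFingerprint]) -> float:
    """Intra-class diversity: mean continuous Tanimoto over all unordered pairs.

    Low values mean a structurally heterogeneous (diverse) class; values near
    one mean near-identical members.  Computed on raw counts.
    """
    members = list(class_members)
    if len(members) < 2:
        raise ValueError("mean pairwise similarity needs at least 2 members")
    sims = [
        tanimoto_continuous(a.counts, b.counts)
        for a, b in itertools.combinations(members, 2)
    ]
    return float(sum(sims) / len(sims))
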