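"""Synthetic fingerprint benchmarks with controllable class diversity.

Real virtual-screening benchmarks pair activity classes (tens to thousands
of actives sharing chemotype substructure) with large decoy backgrounds, and
characterise each class by its diversity — the mean pairwise Tanimoto
similarity of its members, roughly 0.3 for structurally homogeneous classes
down to about 0.1 for heterogeneous ones.  This module emulates that
statistical shape without any chemistry: every activity class owns a
disjoint block of "core" fragments; an active includes each core fragment
with probability ``core_prob`` (count ``1 + Poisson(count_dispersion)``),
plus background fragments drawn uniformly over the whole universe at
``background_rate`` per fragment; decoys draw background only.

``core_prob`` is the diversity dial: :func:`calibrate_diversity` bisects it
until a generated class hits a target mean pairwise Tanimoto.  Generation
pre-draws inclusion uniforms and count noise for all candidate fragments
before applying the inclusion threshold, so for a fixed seed the measured
diversity is exactly monotone in ``core_prob`` and bisection is safe.

The defaults of :func:`default_benchmark_spec` give a compact benchmark
(four classes, two homogeneous near 0.30 and two heterogeneous near 0.10,
1:40 active:decoy ratio) on which a full five-method evaluation runs in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .fingerprints import ActivityLabels, CountFingerprint, mean_pairwise_similarity

__all__ = [
    "ClassSpec",
    "BenchmarkSpec",
    "generate_benchmark",
    "calibrate_diversity",
    "default_benchmark_spec",
]


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic activity class.

    ``core_size`` fragments are reserved exclusively for this class;
    each active carries each of them with probability ``core_prob``.
    """

    class_id: str
    n_actives: int
    core_size: int
    core_prob: float

    def __post_init__(self) -> None:
        if self.n_actives < 1 or self.core_size < 1:
            raise ValueError("class sizes must be >= 1")
        if not 0.0 < self.core_prob <= 1.0:
            raise ValueError(
                f"core_prob must lie in (0, 1], got {self.core_prob}"
            )


@dataclass(frozen=True)
class BenchmarkSpec:
    """Full benchmark recipe; ``seed`` is mandatory for reproducibility."""

    classes: tuple
    n_decoys: int
    seed: int
    fragment_universe: int = 512
    background_rate: float = 0.02
    count_dispersion: float = 0.7

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.fragment_universe < 1:
            raise ValueError("fragment universe must be >= 1")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        if not 0.0 <= self.background_rate < 1.0:
            raise ValueError("background_rate must lie in [0, 1)")
        if self.count_dispersion < 0:
            raise ValueError("count_dispersion must be >= 0")
        total_core = sum(c.core_size for c in self.classes)
        if total_core > self.fragment_universe:
            raise ValueError(
                f"fragment universe of {self.fragment_universe} is too small "
                f"for {total_core} class-core fragments"
            )


def _draw_compound(
    rng: np.random.Generator,
    compound_id: str,
    core_frags: np.ndarray,
    core_prob: float,
    universe: int,
    background_rate: float,
    dispersion: float,
) -> CountFingerprint:
    counts: dict[int, int] = {}
    # pre-draw uniforms and count noise for every candidate so that rng
    # consumption is independent of core_prob (keeps calibration monotone)
    if core_frags.size:
        u = rng.random(core_frags.size)
        noise = rng.poisson(dispersion, core_frags.size) if dispersion > 0 else np.zeros(
            core_frags.size, dtype=int
        )
        for frag, ui, ni in zip(core_frags, u, noise):
            if ui < core_prob:
                counts[int(frag)] = 1 + int(ni)
    if background_rate > 0:
        u_bg = rng.random(universe)
        noise_bg = rng.poisson(dispersion, universe) if dispersion > 0 else np.zeros(
            universe, dtype=int
        )
        hit = np.nonzero(u_bg < background_rate)[0]
        for frag in hit:
            frag = int(frag)
            if frag not in counts:  # a compound's own core count wins
                counts[frag] = 1 + int(noise_bg[frag])
    return CountFingerprint(compound_id, counts)


def generate_benchmark(
    spec: BenchmarkSpec,
) -> tuple[list[CountFingerprint], ActivityLabels]:
    """Generate the library and activity labels described by ``spec``.

    Deterministic given ``spec.seed``: the same spec always yields the same
    library.  Class cores are disjoint fragment blocks carved from a seeded
    shuffle of the universe, so classes with no background share nothing.
    """
    rng = np.random.default_rng(spec.seed)
    universe_perm = rng.permutation(spec.fragment_universe)
    cores: dict[str, np.ndarray] = {}
    offset = 0
    for cls in spec.classes:
        cores[cls.class_id] = universe_perm[offset : offset + cls.core_size]
        offset += cls.core_size

    library: list[CountFingerprint] = []
    classes: dict[str, set] = {}
    for cls in spec.classes:
        members = set()
        for i in range(cls.n_actives):
            cid = f"{cls.class_id}_A{i:04d}"
            library.append(
                _draw_compound(
                    rng,
                    cid,
                    cores[cls.class_id],
                    cls.core_prob,
                    spec.fragment_universe,
                    spec.background_rate,
                    spec.count_dispersion,
                )
            )
            members.add(cid)
        classes[cls.class_id] = members
    empty_core = np.empty(0, dtype=int)
    for i in range(spec.n_decoys):
        cid = f"DEC_{i:05d}"
        library.append(
            _draw_compound(
                rng,
                cid,
                empty_core,
                0.5,
                spec.fragment_universe,
                spec.background_rate,
                spec.count_dispersion,
            )
        )
    return library, ActivityLabels(classes)


def _measured_diversity(
    core_prob: float,
    class_id: str,
    n_actives: int,
    core_size: int,
    fragment_universe: int,
    background_rate: float,
    count_dispersion: float,
    seed: int,
) -> float:
    spec = BenchmarkSpec(
        classes=(ClassSpec(class_id, n_actives, core_size, core_prob),),
        n_decoys=0,
        seed=seed,
        fragment_universe=fragment_universe,
        background_rate=background_rate,
        count_dispersion=count_dispersion,
    )
    library, _ = generate_benchmark(spec)
    return mean_pairwise_similarity(library)


def calibrate_diversity(
    target_mean_tanimoto: float,
    class_id: str = "CAL",
    n_actives: int = 20,
    core_size: int = 40,
    fragment_universe: int = 512,
    background_rate: float = 0.02,
    count_dispersion: float = 0.7,
    seed: int = 0,
    tol: float = 0.02,
    max_iter: int = 30,
) -> ClassSpec:
    """Find the ``core_prob`` whose generated class has the target diversity.

    Bisects ``core_prob`` (at most ``max_iter`` iterations) until the mean
    pairwise Tanimoto of the generated class is within ``tol`` of
    ``target_mean_tanimoto``.  Raises if the target lies outside the
    achievable range for this class shape, reporting the achieved bounds.
    """
    if not 0.0 < target_mean_tanimoto <= 1.0:
        raise ValueError(
            f"target diversity must lie in (0, 1], got {target_mean_tanimoto}"
        )

    def measure(p: float) -> float:
        return _measured_diversity(
            p,
            class_id,
            n_actives,
            core_size,
            fragment_universe,
            background_rate,
            count_dispersion,
            seed,
        )

    lo, hi = 1e-6, 1.0
    f_lo, f_hi = measure(lo), measure(hi)
    if not (f_lo - tol <= target_mean_tanimoto <= f_hi + tol):
        raise ValueError(
            f"target diversity {target_mean_tanimoto} unreachable for this "
            f"class shape; achievable range is [{f_lo:.4f}, {f_hi:.4f}]"
        )
    best_p, best_val = hi, f_hi
    if abs(f_lo - target_mean_tanimoto) < abs(f_hi - target_mean_tanimoto):
        best_p, best_val = lo, f_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = measure(mid)
        if abs(f_mid - target_mean_tanimoto) < abs(best_val - target_mean_tanimoto):
            best_p, best_val = mid, f_mid
        if f_mid < target_mean_tanimoto:
            lo = mid
        else:
            hi = mid
        if abs(f_mid - target_mean_tanimoto) <= tol * 0.5:
            break
    if abs(best_val - target_mean_tanimoto) > tol:
        raise ValueError(
            f"calibration failed: best achieved diversity {best_val:.4f} for "
            f"target {target_mean_tanimoto} (tolerance {tol})"
        )
    return ClassSpec(class_id, n_actives, core_size, best_p)


def default_benchmark_spec(seed: int = 0, calibrate: bool = True) -> BenchmarkSpec:
    """Compact benchmark emulating the homogeneous/heterogeneous class mix.

    Four activity classes of 12 actives each — two homogeneous (diversity
    calibrated to ~0.30) and two heterogeneous (~0.10) — against 1920
    decoys (1:40 active:decoy ratio), 512-fragment universe.  With
    ``calibrate=False`` fixed core probabilities near the calibrated values
    are used instead of running the bisection.
    """
    targets = {"HOM1": 0.30, "HOM2": 0.30, "HET1": 0.10, "HET2": 0.10}
    fallback = {"HOM1": 0.78, "HOM2": 0.78, "HET1": 0.38, "HET2": 0.38}
    classes = []
    for i, (cid, target) in enumerate(targets.items()):
        if calibrate:
            cls = calibrate_diversity(
                target,
                class_id=cid,
                n_actives=12,
                core_size=40,
                seed=seed + i,
            )
        else:
            cls = ClassSpec(cid, 12, 40, fallback[cid])
        classes.append(cls)
    return BenchmarkSpec(
        classes=tuple(classes),
        n_decoys=1920,
        seed=seed,
        fragment_universe=512,
        background_rate=0.02,
        count_dispersion=0.7,
    )
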