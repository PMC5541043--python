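"""Seeded generators of hierarchies, perturbations, and structure-correlated
feature matrices.

These generators stand in for annotated corpora: every metric and the whole
δ pipeline can be exercised without downloading audio or annotations.  A
generated hierarchy mimics a two-level song annotation — Poisson-distributed
section boundaries, a small label alphabet with repetition, fine levels
nested inside coarse ones — and :func:`planted_features` emits feature
matrices whose self-similarity structure follows the hierarchy's deepest
level, emulating the block structure real SSMs exhibit for structured audio.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .annotations import FlatSegmentation, Hierarchy, Segment, sample_labels
from .features import PREPARED_DIMS, FeatureMatrix

MIN_SEGMENT = 0.5  # seconds; generated and jittered segments never get shorter


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic annotation.

    ``boundary_rate`` is the expected number of *additional* interior
    boundaries per minute introduced at each level, so a 3-minute track at
    the default rate has about 7 coarse sections, each further subdivided at
    the fine level — comparable to a pop-song section annotation.
    """

    duration: float = 180.0
    depth: int = 2
    boundary_rate: float = 2.0
    alphabet_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")


def _level_alphabet(level: int, size: int) -> list[str]:
    letters = string.ascii_uppercase if level == 0 else string.ascii_lowercase
    if size <= len(letters):
        base = [letters[i] for i in range(size)]
    else:
        base = [f"{letters[i % len(letters)]}{i // len(letters)}" for i in range(size)]
    return [lbl + "'" * level if level > 1 else lbl for lbl in base]


def _poisson_boundaries(
    rng: np.random.Generator, start: float, end: float, rate_per_minute: float
) -> list[float]:
    span = end - start
    n = rng.poisson(rate_per_minute * span / 60.0)
    pts = sorted(start + span * rng.random(n))
    # enforce a minimum segment length to keep fixtures realistic
    kept: list[float] = []
    prev = start
    for p in pts:
        if p - prev >= MIN_SEGMENT and end - p >= MIN_SEGMENT:
            kept.append(p)
            prev = p
    return kept


def random_hierarchy(spec: SyntheticSpec, nested: bool = True) -> Hierarchy:
    """Generate a random hierarchy, reproducibly under ``spec.seed``.

    Level 1 boundaries are a Poisson process at ``boundary_rate`` per minute
    (plus the track ends); labels are uniform over the level's alphabet, so
    adjacent repeats can occur.  With ``nested=True`` (the default, matching
    the approximately nested SALAMI-style annotations) each deeper level
    subdivides its parent's segments; with ``nested=False`` levels are drawn
    independently, exercising the max-over-levels semantics of the meet.
    """
    rng = np.random.default_rng(spec.seed)
    levels: list[FlatSegmentation] = []
    prev_bounds = [0.0, spec.duration]
    for lvl in range(spec.depth):
        if nested:
            bounds = [0.0]
            for a, b in zip(prev_bounds, prev_bounds[1:]):
                bounds.extend(_poisson_boundaries(rng, a, b, spec.boundary_rate))
                bounds.append(b)
        else:
            bounds = (
                [0.0]
                + _poisson_boundaries(rng, 0.0, spec.duration, spec.boundary_rate * (lvl + 1))
                + [spec.duration]
            )
        alphabet = _level_alphabet(lvl, spec.alphabet_size)
        segs = tuple(
            Segment(a, b, alphabet[rng.integers(len(alphabet))])
            for a, b in zip(bounds, bounds[1:])
        )
        levels.append(FlatSegmentation(segs))
        prev_bounds = bounds
    return Hierarchy(tuple(levels))


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def _permute_labels(h: Hierarchy, rng: np.random.Generator) -> Hierarchy:
    levels = []
    for lvl in h.levels:
        labels = sorted(lvl.label_set)
        perm = rng.permutation(len(labels))
        mapping = {old: f"{labels[perm[i]]}*" for i, old in enumerate(labels)}
        levels.append(
            FlatSegmentation(tuple(Segment(s.start, s.end, mapping[s.label]) for s in lvl.segments))
        )
    return Hierarchy(tuple(levels))


def _duplicate_level(h: Hierarchy, k: int | None, rng: np.random.Generator) -> Hierarchy:
    if k is None:
        k = int(rng.integers(h.depth))
    levels = list(h.levels)
    levels.insert(k + 1, levels[k])
    return Hierarchy(tuple(levels))


def _refine(h: Hierarchy, splits: int, rng: np.random.Generator) -> Hierarchy:
    """Append a new deepest level subdividing every deepest segment into up
    to ``splits + 1`` parts with fresh, globally unique labels."""
    deepest = h.levels[-1]
    segs: list[Segment] = []
    counter = 0
    for s in deepest.segments:
        cuts = sorted(s.start + (s.end - s.start) * rng.random(splits))
        cuts = [c for c in cuts if min(c - s.start, s.end - c) >= 0.05]
        bounds = [s.start] + cuts + [s.end]
        for a, b in zip(bounds, bounds[1:]):
            segs.append(Segment(a, b, f"sub{counter}"))
            counter += 1
    return Hierarchy(tuple(list(h.levels) + [FlatSegmentation(tuple(segs))]))


def _jitter_boundaries(h: Hierarchy, amount: float, rng: np.random.Generator) -> Hierarchy:
    levels = []
    for lvl in h.levels:
        bounds = list(lvl.boundaries)
        for i in range(1, len(bounds) - 1):
            lo = bounds[i - 1] + MIN_SEGMENT / 2
            hi = bounds[i + 1] - MIN_SEGMENT / 2
            if lo >= hi:
                continue
            bounds[i] = float(np.clip(bounds[i] + rng.uniform(-amount, amount), lo, hi))
        segs = tuple(
            Segment(a, b, s.label)
            for (a, b), s in zip(zip(bounds, bounds[1:]), lvl.segments)
        )
        levels.append(FlatSegmentation(segs))
    return Hierarchy(tuple(levels))


def _relabel_noise(h: Hierarchy, fraction: float, rng: np.random.Generator) -> Hierarchy:
    levels = []
    for lvl in h.levels:
        labels = sorted(lvl.label_set)
        segs = []
        for s in lvl.segments:
            if rng.random() < fraction:
                segs.append(Segment(s.start, s.end, labels[rng.integers(len(labels))]))
            else:
                segs.append(s)
        levels.append(FlatSegmentation(tuple(segs)))
    return Hierarchy(tuple(levels))


def perturb(
    h: Hierarchy,
    kind: str,
    amount: float | int | None = None,
    seed: int | None = None,
) -> Hierarchy:
    """Apply a named structural perturbation to a hierarchy.

    Kinds and their ``amount`` semantics:

    * ``permute_labels`` — bijective relabel of every level (amount unused);
      all label-agreement metrics against the original stay 1.
    * ``duplicate_level`` — insert an exact copy of level ``amount`` (0-based;
      random level when omitted); leaves L-scores unchanged.
    * ``refine`` — append a deeper level splitting every deepest segment into
      up to ``amount + 1`` parts (default 1 split) with fresh labels;
      L-recall(original, refined) stays 1.
    * ``jitter_boundaries`` — move interior boundaries by uniform offsets up
      to ``amount`` seconds, clipped to the neighboring boundaries.
    * ``relabel_noise`` — reassign a ``amount`` fraction of segments' labels
      uniformly within the level's label set.
    """
    rng = np.random.default_rng(seed)
    if kind == "permute_labels":
        return _permute_labels(h, rng)
    if kind == "duplicate_level":
        return _duplicate_level(h, None if amount is None else int(amount), rng)
    if kind == "refine":
        return _refine(h, 1 if amount is None else int(amount), rng)
    if kind == "jitter_boundaries":
        return _jitter_boundaries(h, 2.0 if amount is None else float(amount), rng)
    if kind == "relabel_noise":
        return _relabel_noise(h, 0.2 if amount is None else float(amount), rng)
    raise ValueError(f"unknown perturbation kind {kind!r}")


# ---------------------------------------------------------------------------
# Structure-correlated features
# ---------------------------------------------------------------------------

def planted_features(
    h: Hierarchy,
    frame_rate: float = 4.0,
    noise_scale: float = 0.5,
    seed: int | None = None,
) -> dict[str, FeatureMatrix]:
    """Feature matrices whose similarity structure follows a hierarchy.

    For each feature kind, every deepest-level segment label maps to a fixed
    random prototype column; each frame receives its segment's prototype plus
    isotropic Gaussian noise of standard deviation ``noise_scale``.  Output
    dimensions match the real extractors after preparation (tempo 384,
    rhythm 33, chroma 36, MFCC 60) so the matrices feed directly into the
    self-similarity stage.  With ``noise_scale = 0`` the SSM is exactly
    block-valued on same-label frame pairs.
    """
    rng = np.random.default_rng(seed)
    codes = sample_labels(h, frame_rate).labels[-1]
    n_labels = int(codes.max()) + 1
    out = {}
    for kind, dim in PREPARED_DIMS.items():
        protos = rng.normal(size=(dim, n_labels))
        vals = protos[:, codes] + noise_scale * rng.normal(size=(dim, codes.size))
        out[kind] = FeatureMatrix(kind, vals, frame_rate)
    return out


def _has_label_contrast(h: Hierarchy) -> bool:
    """True when every level uses at least two distinct labels."""
    return all(len(lvl.label_set) >= 2 for lvl in h.levels)


def synthetic_corpus(
    n_tracks: int,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
    perturbations: tuple[tuple[str, float], ...] = (
        ("jitter_boundaries", 3.0),
        ("relabel_noise", 0.3),
    ),
) -> list[tuple[Hierarchy, Hierarchy, Hierarchy]]:
    """Generate (planted, annotation_1, annotation_2) triples.

    Each track plants a ground-truth hierarchy and derives two independent
    annotator-like views by applying the given perturbations with
    track-varying strength — mimicking two annotators who agree about an
    underlying structure to a varying degree.  Tracks where any hierarchy
    degenerates to a single label at some level (a constant meet matrix
    carries no ranking evidence) are redrawn, mirroring how multi-annotator
    corpora are sampled from tracks with actual sectional structure.
    """
    base = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    tracks = []
    for i in range(n_tracks):
        while True:
            planted = random_hierarchy(replace(base, seed=int(rng.integers(2**31))))
            strength = (i + 1) / n_tracks
            views = []
            for _ in range(2):
                view = planted
                for kind, amount in perturbations:
                    view = perturb(view, kind, amount * strength, seed=int(rng.integers(2**31)))
                views.append(view)
            if all(_has_label_contrast(h) for h in (planted, *views)):
                break
        tracks.append((planted, views[0], views[1]))
    return tracks


def export_corpus(
    tracks: list[tuple[Hierarchy, Hierarchy, Hierarchy]],
    directory: str | Path,
) -> Path:
    """Write a synthetic corpus to disk as LAB files plus a JSON manifest.

    Each track's two annotator views become one interval-LAB file per level;
    the returned manifest path is directly consumable by
    :func:`hierseg.corpus.corpus_scores`.
    """
    from .annotations import write_annotation

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": "interval_lab", "tracks": {}}
    for i, (_, view_a, view_b) in enumerate(tracks):
        track_id = f"track{i:03d}"
        entry = {}
        for name, h in (("ann1", view_a), ("ann2", view_b)):
            files = [f"{track_id}.{name}.level{k + 1}.lab" for k in range(h.depth)]
            write_annotation(h, [directory / f for f in files])
            entry[name] = files
        manifest["tracks"][track_id] = entry
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
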