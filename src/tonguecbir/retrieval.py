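"""Descriptor index, ranked query answering, and precision/recall evaluation.

An index stores, per image, the dominant-color descriptor, the edge
histograms, and the coarse nine-region color histogram (for the
alternative Euclidean color metric).  A query computes both feature
distances to every entry, converts them to similarities with
per-query empirical maxima (or fixed bounds), fuses them, and returns
the top-k entries sorted by fused similarity, ties broken by image id.

Evaluation uses the standard retrieval counts: ``L`` returned images,
``M`` of them relevant, ``D`` relevant images in the whole database;
precision = M/L and recall = M/D, with relevance meaning "same class
label" (the clinician-assigned category in the original setting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .colorspace import GRAY_COEFF_MODES, rgb_to_hsv
from .dominant_color import (
    GlaParams,
    MainColorDescriptor,
    area_histogram_distance,
    area_probabilities,
    dcd_distance,
    extract_main_colors,
)
from .edge_histogram import EdgeHistogramDescriptor, EhdParams, extract_edge_descriptor
from .similarity import (
    DEFAULT_WEIGHT_COLOR,
    DEFAULT_WEIGHT_TEXTURE,
    THEORETICAL_MAX_COLOR,
    THEORETICAL_MAX_TEXTURE,
    texture_distance,
)

log = logging.getLogger(__name__)


@dataclass
class IndexEntry:
    image_id: str
    class_label: str | None
    color_descriptor: MainColorDescriptor
    edge_descriptor: EdgeHistogramDescriptor
    area_histogram: np.ndarray | None = None

    def __eq__(self, other):
        if not isinstance(other, IndexEntry):
            return NotImplemented
        ah_a, ah_b = self.area_histogram, other.area_histogram
        if (ah_a is None) != (ah_b is None):
            return False
        return (
            self.image_id == other.image_id
            and self.class_label == other.class_label
            and self.color_descriptor == other.color_descriptor
            and self.edge_descriptor == other.edge_descriptor
            and (ah_a is None or np.array_equal(ah_a, ah_b))
        )


@dataclass
class RetrievalIndex:
    entries: list[IndexEntry] = field(default_factory=list)
    gla_params: GlaParams = field(default_factory=GlaParams)
    ehd_params: EhdParams = field(default_factory=EhdParams)
    gray_coeffs_mode: str = "standard"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, image_id: str) -> IndexEntry:
        for e in self.entries:
            if e.image_id == image_id:
                return e
        raise KeyError(image_id)

    @property
    def ids(self) -> list[str]:
        return [e.image_id for e in self.entries]


@dataclass(frozen=True)
class RankedMatch:
    image_id: str
    fused: float
    d_color: float
    d_texture: float


@dataclass(frozen=True)
class QueryResult:
    query_id: str
    records: tuple[RankedMatch, ...]
    w_color: float
    w_texture: float

    @property
    def ranked_ids(self) -> list[str]:
        return [r.image_id for r in self.records]


@dataclass(frozen=True)
class EvalStats:
    L: int
    M: int
    D: int

    @property
    def precision(self) -> float:
        return self.M / self.L

    @property
    def recall(self) -> float:
        return self.M / self.D


def make_entry(
    image_id: str,
    image,
    class_label: str | None = None,
    gla_params: GlaParams = GlaParams(),
    ehd_params: EhdParams = EhdParams(),
    gray_coeffs_mode: str = "standard",
) -> IndexEntry:
    """Extract both descriptors (plus the coarse histogram) for one image."""
    arr = np.asarray(image)
    color = extract_main_colors(arr, gla_params)
    edge = extract_edge_descriptor(
        arr, ehd_params, gray_coeffs=GRAY_COEFF_MODES[gray_coeffs_mode]
    )
    areas = area_probabilities(rgb_to_hsv(arr))
    return IndexEntry(image_id, class_label, color, edge, areas)


def build_index(
    images,
    gla_params: GlaParams = GlaParams(),
    ehd_params: EhdParams = EhdParams(),
    gray_coeffs_mode: str = "standard",
) -> RetrievalIndex:
    """Build an index from ``(image_id, image_or_path, class_label)`` triples.

    Paths that fail to load are skipped with a logged warning; an empty
    result raises ``ValueError``.
    """
    index = RetrievalIndex(
        gla_params=gla_params, ehd_params=ehd_params, gray_coeffs_mode=gray_coeffs_mode
    )
    for image_id, source, label in images:
        if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
            from .cli_io import read_image  # lazy: cli_io imports this module

            try:
                arr = read_image(source)
            except (OSError, ValueError) as exc:
                log.warning("skipping unreadable image %s: %s", source, exc)
                continue
        else:
            arr = np.asarray(source)
        index.entries.append(
            make_entry(image_id, arr, label, gla_params, ehd_params, gray_coeffs_mode)
        )
    if not index.entries:
        raise ValueError("no readable images; index is empty")
    return index


def _query_features(index: RetrievalIndex, image):
    if isinstance(image, IndexEntry):
        return image.color_descriptor, image.edge_descriptor, image.area_histogram
    arr = np.asarray(image)
    color = extract_main_colors(arr, index.gla_params)
    edge = extract_edge_descriptor(
        arr,
        index.ehd_params,
        gray_coeffs=GRAY_COEFF_MODES[index.gray_coeffs_mode],
    )
    areas = area_probabilities(rgb_to_hsv(arr))
    return color, edge, areas


def query(
    index: RetrievalIndex,
    image,
    w_color: float = DEFAULT_WEIGHT_COLOR,
    w_texture: float = DEFAULT_WEIGHT_TEXTURE,
    top_k: int = 9,
    query_id: str = "query",
    color_metric: str = "dcd",
    normalization: str = "empirical",
    dmax_color: float | None = None,
    dmax_texture: float | None = None,
) -> QueryResult:
    """Rank index entries by fused similarity to a query image.

    ``image`` may be a raster (descriptors are extracted with the
    index's parameters) or an :class:`IndexEntry` whose stored
    descriptors are reused.  ``normalization='empirical'`` divides by
    the per-query maximum distance; ``'fixed'`` uses the supplied (or
    theoretical) bounds so scores are comparable across queries.
    """
    if len(index) == 0:
        raise ValueError("empty index")
    if w_color < 0 or w_texture < 0 or abs(w_color + w_texture - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    qcolor, qedge, qareas = _query_features(index, image)

    if color_metric == "dcd":
        d1 = np.array(
            [
                dcd_distance(qcolor, e.color_descriptor, index.gla_params.weights)
                for e in index
            ]
        )
    elif color_metric == "areas":
        d1 = np.array(
            [area_histogram_distance(qareas, e.area_histogram) for e in index]
        )
    else:
        raise ValueError(f"unknown color metric {color_metric!r}")
    d2 = np.array([texture_distance(qedge, e.edge_descriptor) for e in index])

    if normalization == "empirical":
        m1 = float(d1.max())
        m2 = float(d2.max())
    elif normalization == "fixed":
        m1 = dmax_color if dmax_color is not None else THEORETICAL_MAX_COLOR
        m2 = dmax_texture if dmax_texture is not None else THEORETICAL_MAX_TEXTURE
        if d1.max() > m1 or d2.max() > m2:
            raise ValueError("fixed dmax smaller than an observed distance")
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    s1 = 1.0 - d1 / m1 if m1 > 0 else np.ones_like(d1)
    s2 = 1.0 - d2 / m2 if m2 > 0 else np.ones_like(d2)
    fused = w_color * s1 + w_texture * s2

    ids = index.ids
    order = sorted(range(len(index)), key=lambda i: (-fused[i], ids[i]))
    records = tuple(
        RankedMatch(ids[i], float(fused[i]), float(d1[i]), float(d2[i]))
        for i in order[:top_k]
    )
    return QueryResult(query_id, records, w_color, w_texture)


def precision_recall(result: QueryResult, relevant_ids) -> EvalStats:
    """Counts and ratios for one ranked result against a relevant set."""
    relevant = set(relevant_ids)
    L = len(result.records)
    if L == 0:
        raise ValueError("empty result list")
    D = len(relevant)
    if D == 0:
        raise ValueError("relevant set is empty (recall undefined)")
    M = sum(1 for r in result.records if r.image_id in relevant)
    return EvalStats(L=L, M=M, D=D)


def _class_relevant(index: RetrievalIndex, label: str) -> set[str]:
    return {e.image_id for e in index if e.class_label == label}


def pr_curve(
    index: RetrievalIndex,
    query_ids=None,
    w_color: float = DEFAULT_WEIGHT_COLOR,
    w_texture: float = DEFAULT_WEIGHT_TEXTURE,
    color_metric: str = "dcd",
):
    """Average precision/recall at every cutoff L = 1..len(index).

    Queries are indexed images (all of them by default); relevance is
    shared class label (self included).  Returns ``(L, precision,
    recall)`` arrays.
    """
    if any(e.class_label is None for e in index):
        raise ValueError("all index entries need class labels for evaluation")
    queries = (
        index.entries
        if query_ids is None
        else [index.get(qid) for qid in query_ids]
    )
    n = len(index)
    prec = np.zeros(n)
    rec = np.zeros(n)
    for q in queries:
        res = query(
            index, q, w_color, w_texture, top_k=n,
            query_id=q.image_id, color_metric=color_metric,
        )
        relevant = _class_relevant(index, q.class_label)
        hits = np.cumsum([r.image_id in relevant for r in res.records])
        cut = np.arange(1, n + 1)
        prec += hits / cut
        rec += hits / len(relevant)
    prec /= len(queries)
    rec /= len(queries)
    return np.arange(1, n + 1), prec, rec


def evaluate_index(
    index: RetrievalIndex,
    query_ids=None,
    top_k: int = 9,
    w_color: float = DEFAULT_WEIGHT_COLOR,
    w_texture: float = DEFAULT_WEIGHT_TEXTURE,
    color_metric: str = "dcd",
):
    """Mean precision/recall at cutoff ``top_k`` over a query set.

    Returns ``(mean_precision, mean_recall)``; queries default to every
    indexed image, relevance is shared class label.
    """
    if any(e.class_label is None for e in index):
        raise ValueError("all index entries need class labels for evaluation")
    queries = (
        index.entries
        if query_ids is None
        else [index.get(qid) for qid in query_ids]
    )
    precs, recs = [], []
    for q in queries:
        res = query(
            index, q, w_color, w_texture, top_k=top_k,
            query_id=q.image_id, color_metric=color_metric,
        )
        stats = precision_recall(res, _class_relevant(index, q.class_label))
        precs.append(stats.precision)
        recs.append(stats.recall)
    return float(np.mean(precs)), float(np.mean(recs))
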