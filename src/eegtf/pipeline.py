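"""End-to-end pipeline: cohort -> preprocess -> features -> compress -> classify.

Thin orchestration over the library modules, with structured logging of every
stage's shapes and seeds.  Intended both as the programmatic entry point for
a full synthetic-cohort experiment and as the template for running the same
stages on recordings loaded from disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .classify import ClassificationReport, ClassifierSpec, CVConfig, default_roster, run_all
from .cohort import CohortSpec, generate_cohort
from .compress import CompressedVector, compress_cube
from .dataset import PairwiseDataset, build_pairwise, minmax_normalize
from .features import FeatureParams, WindowingConfig, compute_feature_cube
from .preprocess import PreprocessConfig, preprocess_recording
from .recording import EEGRecording

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to run a full synthetic-cohort experiment."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    features: FeatureParams = field(default_factory=FeatureParams)
    cv: CVConfig = field(default_factory=CVConfig)
    pairs: list[tuple[str, str]] | None = None
    roster: list[ClassifierSpec] | None = None


def recordings_to_vectors(recordings: list[EEGRecording],
                          preprocess_cfg: PreprocessConfig | None = None,
                          windowing: WindowingConfig | None = None,
                          params: FeatureParams | None = None
                          ) -> list[CompressedVector]:
    """Preprocess, window, featurize and compress a list of recordings."""
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    vectors = []
    for rec in recordings:
        clean = preprocess_recording(rec, preprocess_cfg)
        cube = compute_feature_cube(clean, windowing, params)
        vec = compress_cube(cube)
        logger.info("subject %s: cube %s -> vector of %d columns",
                    rec.subject_id, cube.values.shape, vec.values.size)
        vectors.append(vec)
    return vectors


def assemble_pairs(vectors: list[CompressedVector],
                   pairs: list[tuple[str, str]] | None = None
                   ) -> list[PairwiseDataset]:
    """Build and min-max normalize each requested pairwise dataset.

    When ``pairs`` is None, every unordered pair of groups present is used,
    with the later group (alphabetically) as the positive class.
    """
    if pairs is None:
        groups = sorted({v.group for v in vectors})
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    return [minmax_normalize(build_pairwise(vectors, a, b)) for a, b in pairs]


def run_pipeline(config: PipelineConfig | None = None) -> ClassificationReport:
    """Run the whole experiment and return the classification report."""
    config = config or PipelineConfig()
    recordings = generate_cohort(config.cohort)
    logger.info("generated %d recordings (seed %d)", len(recordings),
                config.cohort.seed)
    vectors = recordings_to_vectors(recordings, config.preprocess,
                                    config.windowing, config.features)
    datasets = assemble_pairs(vectors, config.pairs)
    for ds in datasets:
        logger.info("pair %s: matrix %s", ds.pair, ds.X.shape)
    roster = config.roster if config.roster is not None else default_roster()
    return run_all(datasets, roster, config.cv)
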