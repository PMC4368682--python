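"""Model/Results front end for the construct–refine–evaluate pipeline.

`HelixBundleModel` bundles the inputs (sequence segmentation, topology,
restraints, evaluation criteria); `fit()` runs construction, plant
optimization and greedy refinement and returns a
`HelixBundleResults` carrying the best structure, its evaluation report,
the refinement trace and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .builder import BundleTopology, GroundTruth, make_fixture
from .errors import ParameterError
from .evaluate import (
    CriteriaConfig,
    EvaluationReport,
    evaluate_model,
    iterative_refine,
    rank_candidates,
    report_table,
)
from .structure import Ensemble, HelixSegmentation, Structure, write_pdb

__all__ = ["HelixBundleModel", "HelixBundleResults"]


@dataclass
class HelixBundleModel:
    """A helix-bundle modelling problem.

    Parameters
    ----------
    topology
        A configured :class:`BundleTopology` (helices + loops attached),
        or a list of candidate topologies to rank.
    segmentation
        Helix segmentation used for classification and refinement moves.
    config
        Evaluation criteria; defaults to the standard battery.
    ground_truth
        Interactions to plant during construction.
    """

    topology: BundleTopology | list[BundleTopology]
    segmentation: HelixSegmentation
    config: CriteriaConfig = field(default_factory=CriteriaConfig)
    ground_truth: GroundTruth = field(default_factory=GroundTruth)

    def __post_init__(self):
        if self.config.segmentation is None:
            self.config.segmentation = self.segmentation

    @classmethod
    def from_structure(cls, structure: Structure,
                       segmentation: HelixSegmentation,
                       config: CriteriaConfig | None = None
                       ) -> "HelixBundleResults":
        """Evaluate an existing structure (no construction step)."""
        config = config or CriteriaConfig()
        if config.segmentation is None:
            config.segmentation = segmentation
        report = evaluate_model(structure, config)
        return HelixBundleResults(structure, report, [report], None)

    def build(self, seed: int = 0, **fixture_kwargs) -> Structure:
        """Construct (and plant-optimize) the candidate structure(s),
        returning the best by composite score when several topologies
        are given."""
        topologies = (self.topology if isinstance(self.topology, list)
                      else [self.topology])
        if not topologies:
            raise ParameterError("no topology given")
        candidates = []
        for t in topologies:
            st, _truth = make_fixture(t, self.ground_truth, seed=seed,
                                      **fixture_kwargs)
            candidates.append(st)
        if len(candidates) == 1:
            return candidates[0]
        ranked = rank_candidates(candidates, self.config)
        return ranked[0][0]

    def fit(self, rounds: int = 50, magnitude: float = 1.5, seed: int = 0,
            initial: Structure | None = None, stop_when=None,
            **fixture_kwargs) -> "HelixBundleResults":
        """Construct (unless `initial` is given) then greedily refine.

        Deterministic for a given seed; `rounds=0` evaluates the built
        structure without refinement.
        """
        structure = initial if initial is not None else self.build(
            seed=seed, **fixture_kwargs)
        best, trace = iterative_refine(structure, self.config, rounds=rounds,
                                       magnitude=magnitude, seed=seed,
                                       stop_when=stop_when)
        return HelixBundleResults(best, trace[-1], trace, self)


class HelixBundleResults:
    """Fitted results: best structure, report, trace, summary table."""

    def __init__(self, structure: Structure, report: EvaluationReport,
                 trace: list[EvaluationReport],
                 model: HelixBundleModel | None):
        self.structure = structure
        self.report = report
        self.trace = trace
        self.model = model

    @property
    def composite_score(self) -> float:
        return self.report.composite_score

    def summary(self) -> pd.DataFrame:
        """One-row metric table (same layout as the multi-model report)."""
        return report_table([self.report])

    def score_trace(self) -> list[float]:
        return [r.composite_score for r in self.trace]

    def save_pdb(self, path) -> None:
        write_pdb(Ensemble.single(self.structure), path)

    def __repr__(self) -> str:
        r = self.report
        return (f"<HelixBundleResults {self.structure.label!r}: "
                f"score={r.composite_score:.3f}, helix={r.helix_content:.1f}%, "
                f"ccl={r.ccl_satisfied}/{r.ccl_total}, "
                f"bridges={r.intra_salt_bridges}+{r.inter_salt_bridges}>")
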