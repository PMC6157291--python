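"""End-to-end alignment: similarity -> construction -> refinement -> report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .construct import AlignParams, Matching, construct_matching
from .evalmetrics import AlignmentReport, build_report
from .netio import (
    PPINetwork,
    SeqSimTable,
    read_annotations,
    read_network,
    read_ontology,
    read_seqsim,
    write_matching,
)
from .simscore import ExpansionScorer, node_similarity

logger = logging.getLogger(__name__)


def align_networks(
    net1: PPINetwork,
    net2: PPINetwork,
    seqsim: SeqSimTable | None = None,
    params: AlignParams | None = None,
) -> tuple[Matching, AlignmentReport]:
    """Run the full two-stage aligner on two in-memory networks.

    The first network must be the smaller one (|V1| <= |V2|); metrics are
    normalised by its size.  Returns the final matching and its report.
    """
    from .refine import refine_loop  # local import: refine depends on evalmetrics

    params = params or AlignParams()
    if net1.n_nodes > net2.n_nodes:
        raise ValueError(
            f"the first network must be the smaller one "
            f"(|V1|={net1.n_nodes} > |V2|={net2.n_nodes})"
        )
    s = node_similarity(
        net1, net2, seqsim, alpha=params.alpha, theta=params.theta, k=params.k
    )
    scorer = ExpansionScorer(
        net1, net2, seqsim, alpha=params.alpha, theta=params.theta, k=params.k
    )
    m0 = construct_matching(net1, net2, s, scorer, params)
    logger.info("initial matching: %d pairs", len(m0))
    rng = np.random.default_rng(params.seed)
    m = refine_loop(m0, net1, net2, seqsim, params, rng)
    report = build_report(m, net1, net2, seqsim)
    return m, report


@dataclass
class RunConfig:
    """File-level configuration for one alignment run."""

    net1_path: str
    net2_path: str
    seqsim_path: str | None = None
    seq_mode: str = "bitscore"
    annotations_path: str | None = None
    obo_path: str | None = None
    out_dir: str = "gmalign-out"
    params: AlignParams = field(default_factory=AlignParams)

    def validate(self) -> None:
        for label, p in (
            ("net1", self.net1_path),
            ("net2", self.net2_path),
            ("seqsim", self.seqsim_path),
            ("annotations", self.annotations_path),
            ("obo", self.obo_path),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")


def run(config: RunConfig) -> tuple[Matching, AlignmentReport]:
    """Load inputs, align, and write mapping/report/provenance files."""
    config.validate()
    net1 = read_network(config.net1_path, "G1")
    net2 = read_network(config.net2_path, "G2")
    if net1.n_nodes > net2.n_nodes:
        logger.info("swapping inputs so the smaller network comes first")
        net1, net2 = net2, net1
    seqsim = None
    if config.seqsim_path:
        seqsim = read_seqsim(config.seqsim_path, config.seq_mode, net1, net2)
    m, report = align_networks(net1, net2, seqsim, config.params)

    if config.annotations_path:
        ann = read_annotations(config.annotations_path)
        dag = read_ontology(config.obo_path) if config.obo_path else None
        report = build_report(m, net1, net2, seqsim, ann, dag)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matching(m, out / "mapping.tsv")
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    provenance = {
        "gmalign_version": __version__,
        "net1": str(config.net1_path),
        "net2": str(config.net2_path),
        "seqsim": config.seqsim_path and str(config.seqsim_path),
        "seq_mode": config.seq_mode,
        "params": {
            "alpha": config.params.alpha,
            "theta": config.params.theta,
            "k": config.params.k,
            "tau": config.params.tau,
            "delta": config.params.delta,
            "patience": config.params.patience,
            "seed": config.params.seed,
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return m, report
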