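"""Summary statistics of the published BioGRID benchmark networks.

Eight physical-interaction PPI networks are the standard benchmark for
global aligners; only their printed node/edge counts and average degrees
are recorded here (the interaction data itself must be obtained from
BioGRID).  These summaries let consistency checks and capacity planning run
without any download.

For six of the eight networks the printed average degree equals 2|E|/|V|
computed from the printed counts; the M. musculus and D. melanogaster rows
are internally inconsistent with their own counts (recorded as printed,
flagged ``consistent=False``).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class NetworkSummary:
    code: str
    organism: str
    n_nodes: int
    n_edges: int
    reported_mean_degree: float
    consistent: bool = True

    @property
    def mean_degree(self) -> float:
        """2|E|/|V| from the recorded counts."""
        return 2.0 * self.n_edges / self.n_nodes


BIOGRID_NETWORKS = {
    "RN": NetworkSummary("RN", "R. norvegicus", 1657, 2330, 2.812),
    "CE": NetworkSummary("CE", "C. elegans", 3134, 5428, 3.464),
    "MM": NetworkSummary("MM", "M. musculus", 4370, 9116, 4.1728, consistent=False),
    "AT": NetworkSummary("AT", "A. thaliana", 5897, 13381, 4.538),
    "SP": NetworkSummary("SP", "S. pombe", 1911, 4711, 4.930),
    "DM": NetworkSummary("DM", "D. melanogaster", 7937, 34753, 8.7579, consistent=False),
    "HS": NetworkSummary("HS", "H. sapiens", 13276, 110528, 16.651),
    "SC": NetworkSummary("SC", "S. cerevisiae", 5831, 77149, 26.462),
}

#: Codes whose printed average degree matches their printed counts.
CONSISTENT_CODES = tuple(
    c for c, s in BIOGRID_NETWORKS.items() if s.consistent
)
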