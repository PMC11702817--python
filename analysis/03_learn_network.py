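"""Learn the Bayesian network over the selected features.

BIC hill-climbing with within-family edge blacklists (mutually exclusive
one-hot siblings may not predict each other), then Dirichlet-smoothed
parameter estimation, with the "unknown" state modelled throughout.
"""
import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
analysis_config = import_module("00_config").analysis_config

from contextrisk.bayesnet import BayesNet
from contextrisk.pipeline import stage_learn


def main() -> None:
    cfg = analysis_config()
    artifacts = stage_learn(cfg)
    net = BayesNet.from_json(Path(artifacts["network"]))
    print(f"Learned network: {len(net.dag.nodes)} nodes, {len(net.dag.edges)} edges")
    for parent, child in sorted(net.dag.edges):
        print(f"  {parent} -> {child}")
    outcome_adjacent = sorted(
        set(net.dag.parents("morbidity")) | set(net.dag.children("morbidity"))
    )
    print(f"Variables directly connected to the outcome: {outcome_adjacent}")


if __name__ == "__main__":
    main()
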