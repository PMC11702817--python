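"""Scan for effect modification of the fetal-sex association.

Within each stratum of a context variable (preexisting diabetes, and
EFW categories where available) the RR of composite morbidity for
female versus male sex is estimated with bootstrap CIs; strata whose
95% intervals do not overlap are flagged, with "reversal" when the
direction of effect flips.
"""
import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
analysis_config = import_module("00_config").analysis_config

from contextrisk.bayesnet import BayesNet
from contextrisk.pipeline import _selected_cohort
from contextrisk.risk import scan_interactions


def main() -> None:
    cfg = analysis_config()
    out = Path(cfg.output_dir)
    net = BayesNet.from_json(out / "network.json")
    cohort = _selected_cohort(cfg)
    contexts = [v for v in ("diabetes", "hdp", "efw_p3to9") if v in net.specs]
    findings = scan_interactions(
        net, cohort, net.dag, "female", contexts, cohort.outcome,
        b=cfg.bootstrap_b, seed=cfg.seeds["bootstrap"] + 99,
    )
    if not findings:
        print("No effect modification of fetal sex detected "
              "(all stratum CIs overlap).")
    for f in findings:
        print(f"Interaction: female x {f.context_var} ({f.flag})")
        for state, (rr, ci) in f.stratum_estimates.items():
            print(f"  {f.context_var}={state}: RR {rr:.2f} "
                  f"({ci.low:.2f}-{ci.high:.2f})")


if __name__ == "__main__":
    main()
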