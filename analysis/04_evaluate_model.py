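"""Evaluate the learned network.

Stratified 80/20 split, validation AUC with a bootstrap CI and the
Youden-optimal threshold, stratified 5-fold cross-validation within the
derivation cohort, and performance on rare ("N of 1") covariate
patterns.
"""
import json
import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
analysis_config = import_module("00_config").analysis_config

from contextrisk.pipeline import stage_evaluate


def main() -> None:
    cfg = analysis_config()
    artifacts = stage_evaluate(cfg)
    report = json.loads(Path(artifacts["evaluation"]).read_text())
    v = report["validation"]
    print(f"Validation AUC {v['auc']:.3f} (95% CI {v['ci_low']:.3f}-{v['ci_high']:.3f}), "
          f"threshold {v['threshold']:.4f}, n={v['n']}")
    cv = report["cross_validation"]
    print(f"5-fold CV mean AUC {cv['mean_auc']:.3f} "
          f"(folds: {', '.join(f'{a:.3f}' for a in cv['fold_aucs'])})")
    rare = report["n_of_1"]
    print(f"N-of-1 scenarios: {rare['n']} validation rows "
          f"({rare['fraction_of_validation_pct']}%)")
    if rare["report"]:
        r = rare["report"]
        print(f"  subset AUC {r['auc']:.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f})")
    elif rare["reason"]:
        print(f"  {rare['reason']}")


if __name__ == "__main__":
    main()
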