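#!/usr/bin/env python
"""Differential-susceptibility confirmation suite for every outcome whose
interaction term is significant (raw p < 0.05): quadratic robustness check,
regions of significance, crossover, PoI, PA, mean-split simple slopes, and
the categorical verdict, with interaction plots."""

import importlib
import json
import sys
from pathlib import Path

from dsgxe.diffsusc import ds_report
from dsgxe.moderation import ModelSpec, fit_model, quadratic_robustness
from dsgxe.plots import interaction_plot

BASE = Path(__file__).resolve().parent.parent / "results" / "cohort"

sys.path.insert(0, str(Path(__file__).resolve().parent))
_fit_step = importlib.import_module("05_fit_interactions")
load_frame, OUTCOMES = _fit_step.load_frame, _fit_step.OUTCOMES


def main() -> None:
    frame = load_frame()
    for outcome in OUTCOMES:
        spec = ModelSpec(outcome=outcome)
        fit = fit_model(frame, spec)
        p_int = float(fit.pvalues[spec.interaction])
        if p_int >= 0.05:
            print(f"{outcome}: interaction p = {p_int:.3f} -> suite skipped")
            continue
        quad = quadratic_robustness(frame, spec)
        report = ds_report(frame, spec, fit, quad.nonlinear_flag)
        report["quadratic_check"] = {"p_x2": quad.p_x2, "p_zx2": quad.p_zx2}
        (BASE / f"ds_report_{outcome}.json").write_text(json.dumps(report, indent=2))
        interaction_plot(frame, spec, fit, report, BASE / f"interaction_{outcome}.svg")
        ros = report["ros"]
        idx = report["indices"]
        print(f"{outcome}: interaction p = {p_int:.4f}; "
              f"RoS [{ros['lower']:.3f}, {ros['upper']:.3f}]; "
              f"crossover {idx['crossover_x']:.3f}; "
              f"PoI {idx['poi']:.3f}; PA {idx['pa']:.3f}; "
              f"nonlinear flag {report['nonlinear_flag']}; "
              f"verdict: {report['verdict']['verdict']}")


if __name__ == "__main__":
    main()
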