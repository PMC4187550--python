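"""A small end-to-end training study: simulate, quantify, analyse.

Generates a pre/post endurance-training arm with a planted +15% whole-fibre
GLUT4 increase, runs every image through the full pipeline, and applies the
repeated-measures analysis cascade.  Takes a couple of minutes.
"""

from glut4quant import analyze_study, quantify_study
from glut4quant.synth import EffectSizes, SynthStudyConfig, generate_study

cfg = SynthStudyConfig(
    n_subjects_per_mode=4, modes=("ET",), replicates=1,
    fibres_per_section_per_type=2,
    effect_sizes={"ET": EffectSizes(intensity=0.15, large_count=0.24,
                                    large_size=0.10, small_size=0.17,
                                    peripheral_intensity=0.35,
                                    peripheral_count_shift=0.15)},
    seed=1)
study = generate_study(cfg)
print(f"simulated {len(study.manifest)} fibre images "
      f"({cfg.n_subjects_per_mode} subjects, pre/post)")

result = quantify_study(study.render, study.manifest)
print(f"quantified {len(result.fibre_metrics)} fibres, "
      f"{int((result.qc.status == 'failed').sum()) if len(result.qc) else 0} "
      "QC failures")

subj = result.fibre_metrics.groupby(["subject_id", "timepoint"]
                                    ).mean_intensity.mean().unstack("timepoint")
change = (subj["post"] / subj["pre"] - 1) * 100
print(f"whole-fibre GLUT4 intensity change: {change.mean():.1f}% "
      f"(planted +15%, SEM {change.sem():.1f})")

report = analyze_study(result.fibre_metrics, result.layer_metrics)
effs = {e["effect"]: e["p"]
        for e in report.whole_fibre["mean_intensity"]["anova"]["effects"]}
print(f"training effect on whole-fibre intensity: p = {effs['timepoint']:.4f}")
entry = report.layers["ET"]["mean_intensity"]
ps = {e["effect"]: e["p"] for e in entry["anova"]["effects"]}
print(f"layer main effect p = {ps['layer_index']:.2e}; "
      f"training x layer interaction p = {ps['timepoint*layer_index']:.2e}")
if "within_layer" in entry:
    sig = sorted(k for k, v in entry["within_layer"].items()
                 if v["significant"])
    print(f"layers with significant within-layer increase: {sig}")
# The interaction is driven by the peripherally concentrated increase:
# the PM layer and the first 1 μm shells respond most.
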