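"""Build a clamp plan for a phantom tumor.

Which segmental arteries must be clamped, how many lobar branches feed the
tumor, the tumor-parenchyma contact surface area, and the R/E/N/L
nephrometry components grading tumor complexity.
"""

import tkp
from tkp.pipeline import build_perfusion_model
from tkp.planning import build_plan_report

bundle = tkp.generate_phantom(n_segmental=3, branch_depth=2,
                              tumor_radius=14.0, rng_seed=11)
tree, tmap = build_perfusion_model(
    bundle.kidney, bundle.sinus_ucs, bundle.vessels, bundle.truth.root_hint
)

report = build_plan_report(
    tmap, bundle.kidney, bundle.sinus_ucs, bundle.tumor, abut_margin_mm=1.0
)

print(f"target segmental arteries : {report.target_segment_ids} "
      f"(clamp these {report.n_target_segments})")
print(f"feeding lobar arteries    : {report.feeding_lobar_ids} "
      f"({report.n_feeding_lobar} branches reach the tumor)")
print(f"contact surface area      : {report.csa_cm2:.2f} cm^2 ({report.csa_method})")
rc = report.renal
print(f"R/E/N/L components        : R={rc.R_points} (diameter {rc.radius_cm:.1f} cm), "
      f"E={rc.E_points} ({rc.exophytic_fraction:.0%} exophytic), "
      f"N={rc.N_points} ({rc.nearness_mm:.1f} mm to sinus), "
      f"L={rc.L_points} ({rc.location_category})")
print(f"nephrometry total         : {rc.total} (4 = simplest, 12 = most complex)")
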