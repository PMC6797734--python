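"""A small synthetic patient cohort with registration perturbations.

Each case draws its own tumour geometry, true overlap, residual size and a
site-profile-specific misalignment that is corrected by registration before
segmentation. The summary mirrors the clinical analysis: gating on V2 < V1
under the reference method, per-combination statistics over the gated subset,
and the count of V2 < V1 cases per combination (90% thresholds retain almost
all cases, 40% thresholds almost none).
"""

import warnings

import numpy as np

import petoverlap as po

warnings.filterwarnings("ignore")

records = po.synth_cohort(8, "mixed", seed=11)
for rec in records:
    print(f"{rec.case_id} [{rec.site_tag:>16}] gated={str(rec.gated):5} "
          f"V1(FLAB)={rec.volumes_v1['FLAB']:5.1f} cm^3 "
          f"V2(FLAB)={rec.volumes_v2['FLAB']:5.1f} cm^3 "
          f"residual misalignment={rec.residual_misalignment_mm:.2f} mm")

summary = po.summarize_cohort(records)
print(f"\ngated {summary.n_gated}/{summary.n_cases} cases (V2 < V1 by FLAB)")
print("cases with V2 < V1 per combination:",
      {k: v for k, v in summary.v2_smaller_counts.items()
       if k in ("7040", "7090", "FLAB")})
dices = [r.metric_grid["FLAB"].dice for r in records]
print(f"FLAB-vs-FLAB Dice across cases: mean {np.mean(dices):.2f}, "
      f"sd {np.std(dices, ddof=1):.2f} (highly variable, as in patients)")
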