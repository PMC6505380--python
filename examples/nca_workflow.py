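"""Noncompartmental analysis of a simulated inhibition study.

Simulates paired control/inhibitor cohorts from a one-compartment oral model,
writes them through the standard CSV layout, runs per-subject NCA, and
compares the group AUC ratio with the static-model expectation.
"""

import tempfile
from pathlib import Path

import numpy as np

from ddipk import (
    DDICohortSpec,
    OralPKParams,
    group_aucr,
    read_profiles,
    run_nca,
    simulate_ddi_cohorts,
    write_profiles,
)

grid = np.concatenate([[0.25, 0.5, 1, 2], np.geomspace(4, 96, 9)])
spec = DDICohortSpec(
    base=OralPKParams(dose=10.0, ka=3.0, ke=0.4, sampling_times=grid,
                      noise_cv=0.1, seed=7),
    f_m=0.85, i_over_ki=21.0, n_per_group=8, inter_subject_cv=0.1,
)
control, treated = simulate_ddi_cohorts(spec)

# round-trip through the on-disk format, as a real study would
csv = Path(tempfile.mkdtemp()) / "cohort.csv"
write_profiles(control + treated, csv)
profiles = read_profiles(csv)

results = [run_nca(p) for p in profiles]
by_arm = {"control": [], "treated": []}
for r in results:
    by_arm[r.group].append(r.auc_inf)

for arm, aucs in by_arm.items():
    print(f"{arm:8s} AUC_inf {np.mean(aucs):8.0f} +/- {np.std(aucs, ddof=1):6.0f} h*ng/ml (n={len(aucs)})")

aucr = group_aucr(by_arm["treated"], by_arm["control"])
print(f"observed AUCR {aucr:.2f} vs static-model expectation {spec.expected_aucr():.2f}")
print()
print("The ratio of mean exposures recovers the inhibition strength that")
print("generated the data, within sampling noise of an 8-per-arm study.")
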