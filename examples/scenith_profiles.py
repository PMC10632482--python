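"""SCENITH metabolic-dependence profiling of one synthetic mDC sample.

Generates per-cell puromycin intensities under the full inhibitor panel for
a sample with known pathway dependencies, reduces them to per-condition
medians and derives the percent-scale parameters.
"""

from immunomet.scenith import compute_scenith_profile
from immunomet.simulate import SyntheticCohortConfig, generate_cell_events, panel_from_events

truth = {"good": {"glucose": 0.40, "mito": 0.80, "fao": 0.25, "glut": 0.30}}
config = SyntheticCohortConfig(
    seed=42, cells_per_condition=5000, sample_sigma=0.0,
    dependence=truth, n_patients={"good": 1},
)

events = generate_cell_events(config, "good", "demo_patient")
panel = panel_from_events(events)
print("median puromycin MFI per condition:")
for cond in ("C", "2DG", "O", "Eto", "Tele", "DGO", "H"):
    print(f"  {cond:>4}: {panel.mfi[cond]:8.1f}")

profile = compute_scenith_profile(panel)
print("\nSCENITH parameters (percent of translation dynamic range):")
for name, value in profile.values.items():
    print(f"  {name:<26} {value:6.2f}")
print(f"  QC flags: {sorted(profile.qc_flags) or 'none'}")
print(
    "\nThe ground truth was glucose 40 / mitochondrial 80 / FAO 25 / "
    "glutaminolysis 30; recovered values land within a few points, and the "
    "complement identities (glucose+FAAO, mito+glycolytic = 100) hold exactly."
)
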