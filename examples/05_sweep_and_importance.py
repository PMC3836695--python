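"""Reduced parameter sweep with SVM feature-removal importance.

Sweeps mitosis rate (MR), cleft contractility (FPP lambda), cleft
cell-cell (CC) and cleft-matrix (CM) contact energies over a small
grid, classifies each combination's final depth into the four cleft
classes (bounds 17.8 / 30.5 / 40.7 um), and ranks parameter importance
by how much cross-validated RBF-SVM accuracy drops when a feature is
removed.  Expect CM to matter least.  The full study-scale grid is
SweepGrid() with 600 combinations x 40 replicates (an overnight batch).
"""

from cleftsim import (SweepGrid, combo_classes, feature_importance,
                      removal_importance, run_sweep)

grid = SweepGrid(mr_values=(0.5, 3.0), fpp_values=(1.0, 10.0, 30.0),
                 cc_values=(1.0, 20.0), cm_values=(1.0, 5.0), replicates=3)
outcomes = run_sweep(grid, mcs=1500, seed=0)
combos = combo_classes(outcomes)
print("combination classes:", combos["label"].value_counts().to_dict())
imp = feature_importance(combos, rng=0, n_per_class=50)
print("\naccuracy drop when each parameter is removed "
      "(higher = more important):")
print(removal_importance(imp).to_string())
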