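"""Reference benchmark values for the three public gene-expression studies.

These are the reported per-gene prediction RMSEs and network confusion
counts for ordinary (ODE) and complex-valued (CVODE) model inference on
the E. coli SOS DNA-repair network (6 genes), a human HeLa cell-cycle
subset (5 genes, 46 time points) and an E. coli M3D subnetwork (8 genes,
35 time points).  The raw expression datasets are external downloads and
are not bundled; these summary numbers serve as inputs when recomputing
the headline metrics (averaged RMSE rows, improvement percentages, and
sensitivity/specificity values).
"""

from __future__ import annotations

SOS_GENES = ["uvrD", "lexA", "umuD", "recA", "uvrA", "polB"]

#: per-gene held-out prediction RMSE, SOS DNA-repair network
SOS_RMSE_ODE = [0.014345, 0.075643, 0.017476, 0.164121, 0.168299, 0.004601]
SOS_RMSE_CVODE = [0.007601, 0.072955, 0.008536, 0.076576, 0.122481, 0.003229]

#: SOS network: 6 genes, 7 gold-standard regulations
SOS_N_GENES = 6
SOS_N_GOLD = 7
SOS_CONFUSION = {"CVODE": {"tp": 7, "fp": 17}, "ODE": {"tp": 5, "fp": 18}}

#: per-gene held-out prediction RMSE, HeLa cell-cycle subset (5 genes)
HELA_RMSE_ODE = [0.227851, 0.11358, 0.363917, 0.340177, 0.328782]
HELA_RMSE_CVODE = [0.125126, 0.066308, 0.123348, 0.2797, 0.10551]

ECOLI_GENES = ["Crp", "araC", "nagC", "chbC", "araE", "araA", "chbA", "chbF"]

#: per-gene held-out prediction RMSE, E. coli M3D subnetwork
ECOLI_RMSE_ODE = [
    0.013349, 0.058062, 0.01153, 0.041527, 0.008005, 0.023222, 0.028299, 0.031919,
]
ECOLI_RMSE_CVODE = [
    0.010013, 0.031771, 0.020923, 0.018565, 0.024344, 0.033139, 0.015565, 0.016927,
]

#: E. coli subnetwork: 8 genes, 15 gold-standard regulations.  FP counts
#: follow from the reported specificities over the 49 negative ordered
#: pairs (Sp = TN/49 with TN + FP = 49): 29/49 -> FP=20, 30/49 -> FP=19.
ECOLI_N_GENES = 8
ECOLI_N_GOLD = 15
ECOLI_CONFUSION = {"CVODE": {"tp": 14, "fp": 20}, "ODE": {"tp": 12, "fp": 19}}
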