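"""Correlational-PPI connectivity for one simulated participant.

Simulates BOLD-like signals for 12 nodes (3 of them hubs that synchronize
with the network during deep events), then runs the cPPI chain: drift
removal, deconvolution, interaction terms per condition, and Fisher-z
matrices. Hub pairs should show stronger coupling in the deep condition.
"""

import numpy as np

from lopnet.connectivity import (
    build_task_regressor,
    compute_ppi_term,
    deconvolve,
    ppi_matrix,
    remove_drift,
)
from lopnet.simulate import NoiseSpec, generate_design, generate_node_timeseries, sample_ground_truth

truth = sample_ground_truth(n_nodes=12, n_participants=1, n_hubs=3,
                            gain_mean=0.8, gain_sd=0.0, seed=0)
design = generate_design(n_events=40, seed=1)
labels = np.array(["deep", "shallow"] * 20)

ts = generate_node_timeseries(design, truth, labels, NoiseSpec(sigma=0.3),
                              seed=2, deep_label="deep")
clean = remove_drift(ts.data, design.tr)
neural = deconvolve(clean, design.tr, ridge_lambda=0.01)

z = {}
for cond in ("deep", "shallow"):
    reg = build_task_regressor(design, cond, labels=labels)
    terms = compute_ppi_term(neural, reg.psi_micro, design.tr, microtime=16)
    z[cond] = ppi_matrix(terms, condition=cond).z

hubs = truth.hub_nodes
iu = np.triu_indices(len(hubs), 1)
hub_pairs = {c: z[c][np.ix_(hubs, hubs)][iu].mean() for c in z}
all_pairs = {c: z[c][np.triu_indices(12, 1)].mean() for c in z}
print(f"planted hubs: {list(hubs)}")
print(f"mean hub-pair Fisher z:  deep {hub_pairs['deep']:.3f}  "
      f"shallow {hub_pairs['shallow']:.3f}")
print(f"mean all-pair Fisher z:  deep {all_pairs['deep']:.3f}  "
      f"shallow {all_pairs['shallow']:.3f}")

# Task-modulated coupling appears as a hub-pair z increase specific to the
# deep condition; the all-pair average barely moves, because only the hubs
# were planted to synchronize with the network's evoked signal.
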