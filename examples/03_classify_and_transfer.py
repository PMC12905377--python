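"""Train the feature-learning network and evaluate treated-cell transfer.

Trains the 1500→512→128→2 network to distinguish control (Het) from
mutant (Hom) ovarian cells, reports test accuracy/macro-F1, then passes
the chaperone-treated cells — never seen in training — through the model
and prints the percentage classified as control.  A high percentage means
the rescued cells look like controls to the classifier.
"""

import numpy as np

from catrace import (generate_cohort, make_default_config, stratified_split,
                     train_feature_net, transfer_fraction_control)
from catrace.network import FeatureNetConfig

cohort = generate_cohort(make_default_config("female", seed=1))
core = cohort.subset(np.isin(cohort.labels, ["HET", "HOM"]))
treated = cohort.subset(cohort.labels == "HOM_TREATED")

split = stratified_split(core.labels, test_fraction=0.2, seed=1)
net, report = train_feature_net(
    core, split, FeatureNetConfig(input_dim=core.n_frames, output_dim=2, seed=1))

print(f"Het/Hom test accuracy: {report.accuracy:.1f}%  macro-F1 {report.macro_f1:.2f}")
print(f"treated cells classified as control: "
      f"{transfer_fraction_control(net, treated):.1f}% of {treated.n_cells}")
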