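"""Where does the classifier look?  Saliency localization.

Builds two paired cohorts: one whose groups differ only in their
ligand-response kinetics, and one differing only in spontaneous (basal)
dynamics.  After training a classifier on each, the per-frame saliency map
should concentrate on the window that actually carries the class signal —
the application window in the first case, the pre-ligand period in the
second.  A localization score > 1 means relevance is denser inside the
expected window than outside it.
"""

from catrace import generate_cohort, stratified_split, train_feature_net
from catrace.network import FeatureNetConfig
from catrace.saliency import grad_cam_saliency, localization_score
from catrace.simulate import make_paired_config

for difference, window_name in (("response", "LH application"),
                                ("basal", "pre-ligand")):
    cohort = generate_cohort(make_paired_config(difference, seed=0))
    split = stratified_split(cohort.labels, seed=0)
    net, report = train_feature_net(
        cohort, split,
        FeatureNetConfig(input_dim=cohort.n_frames, output_dim=2, seed=0))
    smap = grad_cam_saliency(net, cohort)
    grid = cohort.grid
    window = ((grid.lh_start, grid.lh_end) if difference == "response"
              else (0, grid.lh_start))
    score = localization_score(smap, window)
    print(f"groups differ in {difference:8s} -> accuracy {report.accuracy:5.1f}%, "
          f"saliency localization on {window_name} window: {score:.2f}")
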