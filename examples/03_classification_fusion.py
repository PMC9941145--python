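"""Severity classification and multi-view max-pool fusion.

A per-view classifier scores frames into {<25%, >=25%}; view scores fuse to
artery level, artery scores to patient level, by element-wise max over the
per-category scores (renormalised). A severe finding in any one view is never
averaged away.
"""

import numpy as np

from angioscreen import classify as C
from angioscreen import metrics as M
from angioscreen import profiles as P

Xtr, ytr, _ = P.easy_classification_dataset(100, seed=0)
model = C.train_view_classifier(Xtr, ytr,
                                P.easy_classifier_config(seed=0, epochs=40))

Xte, yte, _ = P.easy_classification_dataset(30, seed=99)
score_vectors = C.predict_scores(model, Xte)
scores = np.stack([s.scores for s in score_vectors])
print(f"held-out image-level AUC: {M.roc_auc(scores[:, 1], yte):.3f}")

# fuse three views of one artery, then two arteries into a patient score
views = score_vectors[:3]
artery = C.max_fuse([C.max_fuse(views, 'view')], 'artery')
lca = C.ScoreVector(scores=[0.3, 0.7], level='artery', categories=C.TWO_CAT)
rca = C.ScoreVector(scores=[0.8, 0.2], level='artery', categories=C.TWO_CAT)
patient = C.max_fuse([lca, rca], 'patient')
print(f"artery fused scores {np.round(artery.scores, 3)} -> {artery.label}")
print(f"patient fused scores {np.round(patient.scores, 3)} -> {patient.label}")
# (0.3,0.7) + (0.8,0.2) -> raw max (0.8,0.7) -> (8/15, 7/15): the severe
# evidence from either artery carries through to the patient score
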