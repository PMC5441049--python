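"""Double cross-validation as a stand-in for external validation.

Predictive-accuracy metrics computed on the training data with the
selected model are optimistic.  Nested (double) cross-validation scores
every patient with a model tuned and fit entirely without that patient's
fold; the resulting metrics track what an external validation set would
show.
"""

import survmod as sm
from survmod.metrics import delta_c, uno_c

spec = sm.scenario(6, n=600, p=100)
train, valid, effects = sm.generate_pair(spec, seed=21)
model = sm.develop_model(train, sm.ModelSpec(), seed=4)

tau = 5.0
m_train = sm.evaluate_model(model, sm.standardize(train), tau)
m_valid = sm.evaluate_model(model, valid, tau)
dcv = sm.double_cv_scores(train, sm.ModelSpec(), seed=5)
c_2cv = uno_c(train, dcv.linear_predictor, tau)
dc_2cv = delta_c(train, dcv.mod_score, tau)

print(f"Uno's C, training (1CV, optimistic): {m_train.uno_c:.3f}")
print(f"Uno's C, training (2CV):             {c_2cv:.3f}")
print(f"Uno's C, external validation:        {m_valid.uno_c:.3f}")
print(f"delta-C, training (2CV):             {dc_2cv:.3f}")
print(f"delta-C, external validation:        {m_valid.delta_c:.3f}")
print("\nThe 2CV numbers should sit close to the external-validation column,")
print("well below the optimistic training value.")
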