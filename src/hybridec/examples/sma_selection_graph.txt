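# Causal graph for a motor-function hybrid trial in spinal muscular
# atrophy: baseline covariates (enrollment age, disease type, scoliosis,
# baseline motor score MFM0) cause the 12-month motor score MFM12;
# treatment is randomized within the trial.
treatment: A
outcome: MFM12
covariate: Age
covariate: Type
covariate: Scoliosis
covariate: MFM0
Age -> MFM0
Type -> MFM0
Type -> Scoliosis
Age -> Scoliosis
Age -> MFM12
Type -> MFM12
Scoliosis -> MFM12
MFM0 -> MFM12
A -> MFM12
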