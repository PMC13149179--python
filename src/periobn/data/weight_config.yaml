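# Per-node prior/dataset weighting configuration for the bundled
# periodontal model. Ratio strings are kept verbatim; "priors" weights the
# components of a composite prior, "datasets" weights fused datasets
# (questionnaire : EHR), and "prior_dataset" weights the prior against the
# fused data in the pseudo-count update. "prior_sources" documents where
# each prior component comes from (D = demographic literature, E = expert
# elicitation, U = uniform, M = marginal data prior, conditionals = data
# prior queries).
Age:
  priors: "1:1"
  datasets: "1:20"
  prior_dataset: "1:1"
  prior_sources: [D, "EHR P(age | breed size)"]
Bad breath:
  prior_sources: ["EHR resampled by questionnaire P(bad breath)"]
Biofilm:
  prior_sources: ["EHR resampled by expert P(dental hygiene | biofilm)"]
Bleeding gums:
  prior_sources: [E]
Breed:
  datasets: "1:20"
  prior_dataset: "1:1"
  prior_sources: [D]
Breed size:
  priors: "1:10"
  datasets: "1:2"
  prior_dataset: "1:2"
  prior_sources: [D, M]
Clinical signs:
  priors: "15:1:2"
  prior_sources: [E, "Q P(clinical signs | bleeding gums)", "EHR P(clinical signs | age)"]
Conscious exam:
  priors: "5:1"
  prior_sources: [E, "EHR P(conscious exam | age, breed)"]
Dental conformation:
  priors: "5:1"
  prior_dataset: "1:2"
  prior_sources: [M, "EHR P(dental conformation | head shape, breed size)"]
Dental hygiene:
  datasets: "1:10"
  prior_dataset: "1.5:1"
  prior_sources: [E]
GA exam:
  prior_dataset: "1:10"
  prior_sources: [U]
Gingivitis:
  prior_dataset: "1:10"
  prior_sources: [U]
Head shape:
  priors: "1:10"
  datasets: "1:2"
  prior_dataset: "1:10"
  prior_sources: [D, "EHR P(head shape | breed)"]
Owner awareness:
  prior_sources: [E]
Periodontitis:
  priors: "5:1"
  prior_sources: [E, "EHR P(periodontitis DX under COE or GA | age, breed, dental conformation, gingivitis, biofilm)"]
Periodontitis DX:
  prior_sources: []
Periodontitis DX under COE:
  priors: "5:1"
  prior_sources: [E, "EHR P(periodontitis DX under COE | conscious exam)"]
Periodontitis DX under GA:
  priors: "5:1"
  prior_sources: [E, "EHR P(periodontitis DX under GA | GA exam)"]
Pet compliance:
  prior_sources: [E]
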