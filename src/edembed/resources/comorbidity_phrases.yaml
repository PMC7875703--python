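# Phrase table turning survey comorbidity flags into past-history sentences.
# Keys are the flag column names in the survey-style table; values are the
# free-text wording fed to the text encoder. Editable: wording is a styling
# choice, not part of the model contract.
diabetes: "history of diabetes mellitus"
chf: "history of congestive heart failure"
copd: "history of chronic obstructive pulmonary disease"
ckd: "history of chronic kidney disease"
cancer: "history of malignancy"
hiv: "history of human immunodeficiency virus infection"
dementia: "history of dementia"
cva: "history of cerebrovascular accident"
htn: "history of hypertension"
cad: "history of coronary artery disease"
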