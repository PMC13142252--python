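label	domain	rescue_class	proline_involved	note
A189V	ECD	non_responsive	false	ectodomain trafficking variant; neither mature nor immature band detected, no response to the pharmacoperone
N191I	ECD	marginal	false	ectodomain trafficking variant; marginal increase of the mature band after treatment
D224V	ECD	marginal	false	ectodomain trafficking variant; marginal increase of the mature band after treatment
D408Y	TMD2	rescued	false	robust increase of the mature receptor form after treatment
A419T	TMD2	rescued	false	rescued, though the increase in membrane expression was modest
I423T	TMD2	rescued	false	robust increase of the mature receptor form after treatment
A462P	TMD3	non_responsive	true	only the immature form detected; substitution introduces a proline
P504S	TMD4	non_responsive	true	only the immature form detected; substitution removes a proline
P519T	ECL2	marginal	true	modest but significant increase in M/I ratio; substitution removes a proline
A575V	TMD6	rescued	false	robust increase of the mature receptor form after treatment
P587H	TMD6	rescued	true	modest but significant M/I increase, counted among the rescued set; substitution removes a proline
F591S	TMD6	rescued	false	modest M/I rescue but clearly improved signaling; also reported once as F591I, the S substitution is used consistently elsewhere and adopted here
L597I	ECL3	rescued	false	boundary of TMD6 and extracellular loop 3; robust increase of the mature form
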