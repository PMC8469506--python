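predicted\true,normal,low_grade_dysplasia,high_grade_dysplasia,invasive_cancer
normal,25,2,0,1
low_grade_dysplasia,1,15,1,0
high_grade_dysplasia,5,1,38,0
invasive_cancer,6,0,4,53
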