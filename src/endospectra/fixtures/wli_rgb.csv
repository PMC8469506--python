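predicted\true,normal,low_grade_dysplasia,high_grade_dysplasia,invasive_cancer
normal,13,3,0,2
low_grade_dysplasia,1,11,1,0
high_grade_dysplasia,3,1,30,1
invasive_cancer,0,3,4,39
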