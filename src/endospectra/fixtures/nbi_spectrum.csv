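predicted\true,normal,low_grade_dysplasia,high_grade_dysplasia,invasive_cancer
normal,24,2,1,0
low_grade_dysplasia,1,24,0,1
high_grade_dysplasia,0,1,41,1
invasive_cancer,0,0,3,51
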