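predicted\true,normal,low_grade_dysplasia,high_grade_dysplasia,invasive_cancer
normal,23,2,1,1
low_grade_dysplasia,2,21,1,1
high_grade_dysplasia,0,3,45,3
invasive_cancer,0,2,2,48
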