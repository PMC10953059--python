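code,condition_id
04000100,painful_condition
04000200,painful_condition
04000300,painful_condition
04010100,anxiety_depression
04010200,anxiety_depression
04010300,anxiety_depression
04020100,irritable_bowel_syndrome
04020200,irritable_bowel_syndrome
04020300,irritable_bowel_syndrome
04030100,asthma
04030200,asthma
04030300,asthma
04040100,constipation
04040200,constipation
04040300,constipation
04050100,epilepsy
04050200,epilepsy
04050300,epilepsy
04060100,psoriasis_eczema
04060200,psoriasis_eczema
04060300,psoriasis_eczema
04070100,migraine
04070200,migraine
04070300,migraine
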