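cancer_id,icd10,sex,cases,deaths
colorectum,C18-C20,male,23420,
colorectum,C18-C20,female,20282,
mouth_pharynx_larynx,C00-C10;C12-C13;C14;C32,male,6855,
mouth_pharynx_larynx,C00-C10;C12-C13;C14;C32,female,2462,
oral_pharyngeal,C00-C14,male,4839,
oral_pharyngeal,C00-C14,female,1716,
esophagus,C15,male,1710,
esophagus,C15,female,684,
stomach,C16,male,8458,
stomach,C16,female,6098,
stomach_cardia,C16.0,male,1269,
stomach_cardia,C16.0,female,915,
lung,C34,male,27554,
lung,C34,female,13328,
liver,C22,male,8978,
liver,C22,female,4034,
endometrium,C54.1,female,8335,
diet_related,,male,77396,
diet_related,,female,55341,
all_cancers,,male,194754,
all_cancers,,female,181857,
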