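{
 "cohort_results.tsv": "92cfe95e18dfdd77497efffec52b76997ca3de95f49db34ba0adbe840afbd24b",
 "example_false_positives.tsv": "acc805a57b034c758ff48aa2989227488fa5bf491dce2d20d83db5a8dcdc8f5a",
 "fbn1_genotype_phenotype.tsv": "40e9f9af6ea02583429de3d6ec07321f0e5e43e2e82cd623ae08372b83618809",
 "mutations.tsv": "dcf65a06626dead816463af46cdca6b9356784cdcde56343e38f6e9a739cc20e",
 "panel_genes.tsv": "ae019b882a26940a037113fe39362a16a841e9bd4d2e0309453639004b6afff3",
 "reclassified_variants.tsv": "ce1bb8680b83e23aaa8e852617a0036319b8f818c2483f8c20ec9b10cf2b5909"
}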