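# Default trigger-term rules for the four-way functional classification.
# Lower precedence wins when a protein's annotation terms match several
# categories.  metastasis_unknown is the fallback and needs no terms.
# Edit or replace via --rules; the file is an explicit stand-in for manual
# curation of GO / KEGG / functional-description evidence.
rules:
  - category: immune_modulation
    precedence: 1
    terms:
      - antigen
      - immune
      - immunosuppress
      - cytokine
      - interleukin
      - complement
      - mhc
      - proteasome
      - t cell
      - t-cell
      - macrophage
      - interferon
  - category: metabolic_acidification
    precedence: 2
    terms:
      - glycolysis
      - gluconeogenesis
      - lactate
      - acidification
      - proton transport
      - atpase
      - carbonic anhydrase
      - tca cycle
      - citrate cycle
      - oxidative phosphorylation
      - metabolic
  - category: oncogenic_driver
    precedence: 3
    terms:
      - kinase
      - oncogene
      - proliferation
      - growth factor
      - signaling
      - signal transduction
      - ubiquitin
      - cell cycle
      - gtpase
      - transcription factor
  - category: metastasis_unknown
    precedence: 4
    terms: []
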