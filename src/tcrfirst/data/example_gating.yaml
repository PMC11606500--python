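# Illustrative gating hierarchy with placeholder marker sets.
# These gene lists are examples for synthetic data and documentation only;
# supply curated signatures for real analyses.
name: T
positive_signatures:
  - [CD3D, CD3E, CD3G, CD2]
children:
  - name: CD4
    positive_signatures:
      - [CD4, IL7R, CCR7, TCF7]
    children:
      - name: Treg
        positive_signatures:
          - [FOXP3, IL2RA, CTLA4]
      - name: CD4_effector
        positive_signatures:
          - [IFNG, TNF, IL2]          # TH1 cytokines
  - name: CD8
    positive_signatures:
      - [CD8A, CD8B]
    children:
      - name: CD8_cytotoxic
        positive_signatures:
          - [GZMB, PRF1, NKG7, KLRD1]
      - name: CD8_memory
        positive_signatures:
          - [GZMK, CCR7, SELL]
  - name: cycling
    positive_signatures:
      - [MKI67, TOP2A, STMN1]
  - name: immune_checkpoint
    positive_signatures:
      - [PDCD1, HAVCR2, LAG3, TIGIT]
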