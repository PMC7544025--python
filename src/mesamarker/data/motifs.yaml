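# Default cis-element consensus dictionary for promoter scanning.
#
# Published consensus strings for common plant promoter elements, written
# with IUPAC ambiguity codes (W={A,T}, R={A,G}, Y={C,T}, ...).  This list is
# editable configuration, not a claim of equivalence with any motif
# database's internal definitions: curated scanners use proprietary pattern
# sets, so absolute counts will differ.  What the pipeline reproduces is the
# analysis shape -- per-species hit counts compared between groups.
motifs:
  - name: TATA-box
    consensus: TATAWAW
  - name: CAAT-box
    consensus: CCAAT
  - name: ABRE
    consensus: ACGTG
  - name: G-Box
    consensus: CACGTG
  - name: GATA-motif
    consensus: WGATAR
  - name: Box4
    consensus: ATTAAT
  - name: TGA-element
    consensus: AACGAC
  - name: AuxRR-core
    consensus: GGTCCAT
  - name: circadian
    consensus: CAANNNNATC
  - name: Sp1
    consensus: GGGCGG
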