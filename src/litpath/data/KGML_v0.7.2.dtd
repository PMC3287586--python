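<!--
  KGML v0.7.2-compatible DTD (pathway / entry / graphics / relation /
  subtype / reaction subset used by litpath).  One extension relative to
  KEGG's published grammar: relation carries an optional `evidence`
  attribute holding a space-separated PMID list, so that curated pathways
  round-trip losslessly.  Documents without it remain valid.
-->
<!ELEMENT pathway (entry*, relation*, reaction*)>
<!ATTLIST pathway
    name    CDATA #REQUIRED
    org     CDATA #REQUIRED
    number  CDATA #IMPLIED
    title   CDATA #IMPLIED
    image   CDATA #IMPLIED
    link    CDATA #IMPLIED>

<!ELEMENT entry (graphics*, component*)>
<!ATTLIST entry
    id        CDATA #REQUIRED
    name      CDATA #REQUIRED
    type      (ortholog|enzyme|reaction|gene|group|compound|map|brite|other) #REQUIRED
    link      CDATA #IMPLIED
    reaction  CDATA #IMPLIED>

<!ELEMENT graphics EMPTY>
<!ATTLIST graphics
    name     CDATA #IMPLIED
    x        CDATA #IMPLIED
    y        CDATA #IMPLIED
    coords   CDATA #IMPLIED
    type     (rectangle|circle|roundrectangle|line) #IMPLIED
    width    CDATA #IMPLIED
    height   CDATA #IMPLIED
    fgcolor  CDATA #IMPLIED
    bgcolor  CDATA #IMPLIED>

<!ELEMENT component EMPTY>
<!ATTLIST component
    id CDATA #REQUIRED>

<!ELEMENT relation (subtype*)>
<!ATTLIST relation
    entry1   CDATA #REQUIRED
    entry2   CDATA #REQUIRED
    type     (ECrel|PPrel|GErel|PCrel|maplink) #REQUIRED
    evidence CDATA #IMPLIED>

<!ELEMENT subtype EMPTY>
<!ATTLIST subtype
    name  CDATA #REQUIRED
    value CDATA #REQUIRED>

<!ELEMENT reaction (substrate|product)*>
<!ATTLIST reaction
    id    CDATA #REQUIRED
    name  CDATA #REQUIRED
    type  (reversible|irreversible) #REQUIRED>

<!ELEMENT substrate (alt?)>
<!ATTLIST substrate
    id   CDATA #REQUIRED
    name CDATA #REQUIRED>

<!ELEMENT product (alt?)>
<!ATTLIST product
    id   CDATA #REQUIRED
    name CDATA #REQUIRED>

<!ELEMENT alt EMPTY>
<!ATTLIST alt
    name CDATA #REQUIRED>
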