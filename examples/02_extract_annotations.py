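"""Extract MIRIAM annotation links from an RDF annotation block.

Each qualifier element (bqbiol:is, bqmodel:isDescribedBy, ...) wraps a Bag
of urn:miriam resources; extraction flattens them into (subject,
qualifier, namespace, external id) tuples, percent-decoding ids once.
"""

from sblink import extract_annotation_links, parse_miriam_urn
from sblink.records import SbaseRecord

print(parse_miriam_urn("urn:miriam:kegg.compound:C00074"))
print(parse_miriam_urn("urn:miriam:obo.go:GO%3A0006096"))  # decoded colon

ANNOTATION = """
<annotation>
 <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
          xmlns:bqbiol="http://biomodels.net/biology-qualifiers/"
          xmlns:bqmodel="http://biomodels.net/model-qualifiers/">
  <rdf:Description rdf:about="#meta1">
   <bqbiol:is><rdf:Bag>
     <rdf:li rdf:resource="urn:miriam:kegg.pathway:tbr00010"/>
     <rdf:li rdf:resource="urn:miriam:taxonomy:5691"/>
   </rdf:Bag></bqbiol:is>
   <bqmodel:isDescribedBy><rdf:Bag>
     <rdf:li rdf:resource="urn:miriam:pubmed:11415442"/>
   </rdf:Bag></bqmodel:isDescribedBy>
  </rdf:Description>
 </rdf:RDF>
</annotation>
"""

record = SbaseRecord(id="model-1", annotation=ANNOTATION)
for link in extract_annotation_links(record):
    print(f"{link.qualifier.value:14s} {link.family.value:7s} "
          f"{link.namespace}:{link.external_id}")
# The qualifier states how strong the match is ("is" = exact counterpart);
# the family tells whether it describes the model or the biology.
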