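# Default annotation vocabulary (slot -> predicate IRI).
# Pass an edited copy to load_vocabulary() to read a different dialect.
chemical: http://purl.org/modeldiscovery/annot#hasChemicalEntity
entity_class: http://purl.org/modeldiscovery/annot#ModelEntity
gene: http://purl.org/modeldiscovery/annot#hasGene
located_in: http://purl.org/modeldiscovery/annot#isLocatedIn
mediator: http://purl.org/modeldiscovery/annot#hasMediatorParticipant
model_class: http://purl.org/modeldiscovery/annot#Model
model_name: http://purl.org/modeldiscovery/annot#hasName
model_organ: http://purl.org/modeldiscovery/annot#forOrgan
model_workspace: http://purl.org/modeldiscovery/annot#inWorkspace
order: http://purl.org/modeldiscovery/annot#hasOrder
property: http://purl.org/modeldiscovery/annot#hasPhysicalProperty
reference_term: http://purl.org/modeldiscovery/annot#hasReferenceTerm
sink: http://purl.org/modeldiscovery/annot#hasSinkParticipant
source: http://purl.org/modeldiscovery/annot#hasSourceParticipant
species: http://purl.org/modeldiscovery/annot#hasSpecies
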