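"""Curate a clinical code list: search, dual annotation, file round-trip.

Builds a heart-failure Read code list from a term dictionary the way a
curation team would: pattern search with synonyms, two independent clinician
classifications reconciled into a consensus, then serialization to the
metadata-bearing text format used for dissemination.
"""

from ehrphen import (
    AnnotationSet,
    CodeList,
    CodeListEntry,
    merge_annotations,
    read_codelist,
    search_terms,
    toy_dictionaries,
    write_codelist,
)

dictionary = toy_dictionaries("heart failure")["READ"]
hits = search_terms(dictionary, ["heart failure", "ventricular failure"])
print(f"search matched {len(hits)} of {len(dictionary)} dictionary terms")

# two clinicians classify independently; disagreements go to a third
a = AnnotationSet("clinician_a", {t: "incident" for t in hits})
b_map = {t: "incident" for t in hits}
b_map[hits[0]] = "possible"  # one disagreement
b = AnnotationSet("clinician_b", b_map)
consensus, disagreements = merge_annotations(a, b)
print(f"{len(consensus)} consensus terms, {len(disagreements)} to adjudicate")

codelist = CodeList(
    metadata={
        "name": "heart failure (READ)",
        "version": "1.0",
        "authors": "clinician_a; clinician_b",
        "timestamp": "2020-01-01T00:00:00",
        "terminology": "READ",
    },
    entries=[CodeListEntry(t, c) for t, c in consensus.items()],
)
write_codelist(codelist, "/tmp/hf_read.codelist.txt")
back = read_codelist("/tmp/hf_read.codelist.txt")
assert back == codelist
print(f"round-tripped {len(back)} entries through the code-list file format")
# the counts show how much of the dictionary the search strategy captured
# and how much clinician disagreement the consensus step had to resolve
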