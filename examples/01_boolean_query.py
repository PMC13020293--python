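"""Build a boolean alias-group query and measure its keyword specificity.

Synonyms are OR-ed within each group and groups are AND-ed; specificity
is the mean phrase length in characters across all phrases.
"""

from litmap import SearchSpec, build_boolean_query, keyword_specificity

spec = SearchSpec.from_groups(
    [
        ["Maternal Pain", "Pain during pregnancy"],
        ["Postpartum depression", "Postnatal depression"],
    ]
)

print("query:", build_boolean_query(spec))
print(f"keyword specificity: {keyword_specificity(spec):.2f} characters/phrase")
# A higher specificity means longer, more specific phrases; here the
# four phrases average 18.75 characters.
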