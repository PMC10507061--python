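"""Build geographic and linguistic proximity matrices for a toy set of nations.

Three nations: two neighbouring ones sharing closely related languages, and
a distant one from an unrelated language family.
"""

import pandas as pd

from galton import (NationTable, LanguageTaxonomy, SpeakerTable,
                    geographic_proximity_matrix, linguistic_proximity_matrix)

nations = NationTable(pd.DataFrame({
    "nation_id": ["Aland", "Bland", "Cland"],
    "capital_lat": [46.0, 48.0, -35.0],
    "capital_lon": [10.0, 14.0, 149.0],
    "continent": ["Europe", "Europe", "Oceania"],
    "majority_family": ["Indo-European", "Indo-European", "Austronesian"],
}))

# rooted taxonomy; branch lengths are irrelevant, only node depth matters
taxonomy = LanguageTaxonomy.from_newick(
    "(((langA,langB)west,langC)Indo-European,((langD,langE)poly)Austronesian);")

speakers = SpeakerTable(pd.DataFrame({
    "nation_id": ["Aland", "Bland", "Bland", "Cland"],
    "language_id": ["langA", "langB", "langC", "langD"],
    "share": [1.0, 0.8, 0.2, 1.0],
}))

geo = geographic_proximity_matrix(nations)
ling = linguistic_proximity_matrix(taxonomy, speakers)

print("Geographic proximity (1 = closest pair of capitals, 0 = most distant):")
print(pd.DataFrame(geo.values, index=geo.ids, columns=geo.ids).round(3))
print()
print("Linguistic proximity (speaker-share-weighted relatedness, 0..1):")
print(pd.DataFrame(ling.values, index=ling.ids, columns=ling.ids).round(3))
print()
print("Aland-Bland are linguistically close (related languages, shared family);"
      "\nCland's languages only meet the others at the root, so proximity is 0.")
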