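"""Chemical half of the pipeline: peak matching and the 7-criterion key.

Zero-noise peak tables are matched to the reference compound library by
retention time (+/- 0.05 min), the seven presence/absence criteria are
evaluated per sample, and each sample is assigned the cluster of its nearest
reference profile.  The panel spreads over the six chemical clusters, and
marker-compound selection flags the seven discriminant compounds.
"""

from lavauth import (
    PANEL,
    evaluate_criteria,
    generate_fixture_set,
    match_peaks,
    select_marker_compounds,
    zero_noise_config,
)
from lavauth.chemo import assign_cluster

fixtures = generate_fixture_set(zero_noise_config(seed=1))
library, key = fixtures.library, fixtures.key

print("sample            criteria (c1..c7)          cluster")
for taxon in PANEL:
    matched = match_peaks(fixtures.peak_tables[taxon.taxon_id], library)
    profile = evaluate_criteria(matched, library)
    assignment = assign_cluster(profile, key, sample_id=taxon.taxon_id)
    marks = " ".join("x" if c else "." for c in profile.as_tuple())
    print(f"{taxon.taxon_id:<17} {marks:<26} {assignment.cluster}")

selected = select_marker_compounds(list(fixtures.peak_tables.values()), library)
print(f"\nmarker compounds ({len(selected)}):",
      [(cid, library.by_id[cid].name) for cid in sorted(selected)])
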