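"""Choosing the caller dyad for each playback condition.

For a given subject, the six experimental conditions prescribe a pattern
of friendship and kinship between the two callers (and between each
caller and the subject).  The selector returns the dyad satisfying the
pattern, or reports the condition infeasible — which happens by design
for central subjects in conditions 3 and 4.
"""

import troopkit as tk

troop = tk.gen_troop_observations(tk.TroopSimSpec(seed=21))
assoc = tk.build_association_matrix(troop.scans)
kin = tk.kinship_matrix(troop.spec.matrilines)
cent = tk.eigenvector_centrality(assoc)

labels = {
    1: "friend A vs A's friend B",
    2: "friend A vs mutual non-friend B",
    3: "two mutual friends, both strangers to the subject",
    4: "two strangers to everyone involved",
    5: "matriarch vs her kin",
    6: "matriarch vs non-kin",
}
for subject in list(assoc.index)[:4]:
    role = "central" if subject in cent.central_set else "peripheral"
    print(f"\nsubject {subject} ({role}):")
    for cond in range(1, 7):
        dyad = tk.select_condition_dyads(subject, assoc, kin,
                                         troop.spec.sexes, cent, cond,
                                         ranks=troop.spec.true_ranks)
        picked = f"{dyad[0]} + {dyad[1]}" if dyad else "infeasible"
        print(f"  condition {cond} ({labels[cond]}): {picked}")
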