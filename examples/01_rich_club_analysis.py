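"""Build a group connectome from synthetic subjects and test its rich club.

Generates a cohort of geometric connectomes with 15 planted, spatially
distributed hubs, thresholds them into a group-representative network
(consistency >= 30%, top 10% of edges by median weight), and compares the
rich-club coefficient against degree-preserving rewired nulls.
"""

import numpy as np

import hubwire

spec = hubwire.SyntheticCohortSpec(n_nodes=150, n_subjects=20, richclub_boost=0.8, seed=1)
cohort = hubwire.simulate_cohort_connectomes(spec)
conn = hubwire.build_group_connectome(cohort.sc, density_target=0.10)

deg = conn.degrees
print(f"group connectome: {conn.n_nodes} nodes, {conn.n_edges} edges")
print(f"planted hub degrees: {np.sort(deg[cohort.hubs])}")
print(f"max non-hub degree:  {np.delete(deg, cohort.hubs).max()}")

lo = int(np.delete(deg, cohort.hubs).max())
hi = int(np.percentile(deg[cohort.hubs], 33))
curve = hubwire.normalized_rich_club_curve(conn, ks=np.arange(lo, hi), n_null=200, seed=0)

print("\n  k   phi(k)  <phi_rand>  Phi_norm       p")
for k, phi, nm, pn, p in zip(curve.k, curve.phi, curve.null_mean, curve.phi_norm, curve.p):
    print(f"{k:4d}  {phi:.3f}   {nm:.3f}      {pn:.3f}   {p:.4f}")
print(
    "\nPhi_norm > 1 with p < 0.05 at every threshold that isolates the "
    "planted hubs: the club is denser than its degree sequence predicts."
)
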