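# podnet

Activity-delineated social network analysis for gambit-of-the-group
sighting data.

Field studies of fission–fusion societies — bottlenose dolphins being the
canonical case — record *sightings*: timestamped groups of photo-identified
individuals engaged in a predominant behavioural state (socializing,
travelling, foraging).  Under the gambit of the group, all members of a
sighted group are assumed to be associating.  A single pooled association
network can mask how social structure changes with behaviour: animals may
socialize in large, tightly-knit communities yet forage alone.  `podnet`
builds and compares association networks *per activity* so that such
state-dependent structure becomes measurable.

The pipeline, designed for shallow-survey dolphin datasets but generic
over any grouped sighting records:

1. **Filters** — dependent calves are removed from group memberships, and
   within-day resightings are excluded (any member seen < 1 h earlier, or
   all members already seen that day).
2. **Association networks** — for each activity (and for all sightings
   pooled), a simple undirected weighted graph over individuals sighted at
   least a threshold number of times (3 by convention), with edge weights
   the half-weight index

   HWI = X / (X + (Y_a + Y_b)/2),

   where X counts sightings containing both individuals and Y_a, Y_b those
   containing only one; HWI is 0 for pairs never seen together, 1 for
   pairs always together, and is insensitive to the sizes of groups
   containing neither individual.
3. **Metrics** — average degree, average strength, average edge weight,
   number of connected components, average (unweighted) clustering
   coefficient, plus per-activity group-size statistics.
4. **Preferential-association test** — a data-stream permutation test:
   checkerboard swaps of the group-by-individual incidence matrix preserve
   every group size and every individual's sighting frequency; an elevated
   observed SD/CV of the HWI distribution relative to the permuted null
   indicates preferred and avoided companions.  The chain uses the
   Besag–Clifford serial layout, making the rank p-values exactly valid at
   any chain length.
5. **Metric randomization** — degree-preserving double-edge-swap rewiring
   with reshuffled edge weights; metrics the null conserves by
   construction are flagged as untestable rather than given p-values.
6. **Communities and overlap** — WalkTrap community detection with HWI
   weights, and cross-network community overlap measured by the variation
   of information VI(P,Q) = H(P) + H(Q) − 2 I(P;Q) (smaller VI = larger
   overlap).
7. **Group-size comparisons** — pairwise two-sided Mann–Whitney U tests
   between activity classes.

A synthetic survey generator (`podnet.simulate`) emulates the study
conditions — ~150 individuals in 8 latent communities, ~300 sightings over
124 days, socializing groups largest and foraging groups smallest, strong
within-community preference while socializing/travelling and none while
foraging, imperfect photo-identification — so the entire pipeline is
testable without field data, including type-I calibration and
power/recovery studies against the planted ground truth.

## Worked example

```bash
podnet simulate --seed 42 --out survey
cat > config.yaml <<'YAML'
sightings_path: survey/sightings.csv
registry_path: survey/registry.csv
out_dir: results
n_permutations: 20000
n_random: 1000
randomization_metrics: [average_clustering, n_connected_components]
YAML
podnet run-all --config config.yaml --seed 1
podnet report --run-dir results
```

prints (abridged):

```
280 sightings / 111 days / 150 individuals
    forage: V=64 E=188  deg=5.88  strength=1.490 w=0.254 C=1 clust=0.319 comms=8 p_mean_low=0.6234 p_cv_high=0.5401
   overall: V=150 E=1182 deg=15.76 strength=3.273 w=0.208 C=1 clust=0.485 comms=8 p_mean_low=0.2531 p_cv_high=0.0001
 socialize: V=32 E=111  deg=6.94  strength=3.670 w=0.529 C=4 clust=0.963 comms=4 p_mean_low=0.9988 p_cv_high=0.0001
    travel: V=55 E=152  deg=5.53  strength=2.080 w=0.376 C=9 clust=0.661 comms=9 p_mean_low=0.9647 p_cv_high=0.00025
community overlap (VI; smaller = larger overlap):
    forage:  0.000  4.710  3.472  3.662
   overall:  4.710  0.000  3.663  3.227
 socialize:  3.472  3.663  0.000  3.048
    travel:  3.662  3.227  3.048  0.000
```

Reading it: socializing happens in few, dense, strongly-weighted
communities (highest edge weight 0.529 and clustering 0.963); foraging is
diffuse and shows no preferential association (CV p-value 0.54, vs
0.0001–0.00025 for the other networks); and the socialize and travel
networks share the most community structure (smallest VI, 3.048 bits).
Each number in the report is recomputable from the intermediates written
to `results/` (GraphML networks, partition CSVs, null-model JSONs).

The library surface mirrors the CLI: `read_sightings`,
`filter_dependent_calves`, `filter_resights`, `build_activity_network`,
`network_metrics`, `permute_group_memberships`, `edge_rearrangement_null`,
`walktrap_partition`, `variation_of_information`,
`mann_whitney_group_sizes`, `simulate_study`, `run_pipeline`.

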