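# dnbkit

Tipping-point detection in replicated time-course expression data via a
criticality index over gene groups, with an integrated network/pathway
ranking of the selected group's members and a synthetic-data generator for
end-to-end testing.

For a gene group at one timepoint (all statistics taken across that
timepoint's replicates):

```
CI = sqrt(size) * (PCC_in / PCC_out) * SD_in
```

where `SD_in` is the mean per-gene standard deviation, `PCC_in` the mean
absolute Pearson correlation of within-group pairs, and `PCC_out` the mean
absolute Pearson correlation of group-to-background pairs. A group whose CI
rises sharply at one timepoint — strong, coordinated fluctuation combined
with decoupling from the rest of the transcriptome — marks an approaching
state transition. The dominant group is found per timepoint by
average-linkage hierarchical clustering of candidate genes on the distance
`1 - |PCC|`, scoring every cluster above a minimum size, and taking the
(cluster, timepoint) pair with the globally maximal CI.

## Modules

| module | contents |
| --- | --- |
| `dnbkit.io_expr` | expression matrix + sample metadata, GMT gene sets, TSV/SIF edge lists, result tables |
| `dnbkit.synthetic_data` | one-factor generator with a planted group/transition, closed-form CI oracle |
| `dnbkit.de_screen` | one-vs-rest Welch screen with BH adjustment; 2^-ddCt utility |
| `dnbkit.dnb_core` | per-timepoint group statistics, CI, dominant-group search, transition call |
| `dnbkit.ranking` | intra-group network-degree index, pathway-hit index, integrated rank |
| `dnbkit.cli` | `simulate` / `screen` / `dnb` / `rank` / `full` subcommands |

The Welch screen is a deliberately simple stand-in for a count-model
differential-expression pipeline: it only produces a candidate list for the
group search, and the `dnb` stage also accepts an explicit candidate list
(`--candidates`) to bypass it.

## CLI

Every stage is a subcommand; `full` runs them end to end from one YAML
config:

```yaml
# config.yaml
seed: 7
simulate:            # or: input: {matrix: expr.tsv, metadata: samples.tsv, scale: log}
  n_genes: 60
  dnb_size: 20
  n_timepoints: 5
  n_replicates: 10
  t_star: 4
  sd_boost: 3.0
  rho_in:  [0.1, 0.1, 0.1, 0.8, 0.1]
  rho_out: [0.3, 0.3, 0.3, 0.05, 0.3]
  coupled_fraction: 0.3
  de_fraction: 0.5
  de_shift: 3.0
screen: {q_threshold: 0.05}
dnb: {min_group_size: 5, cut_height: 0.5, background: all}
rank: {network: net.tsv, gmt: sets.gmt, total_pathways: 185}
```

```bash
dnbkit full --config config.yaml --seed 7 --out-dir out/
```

writes `expression.tsv` / `samples.tsv` / `ground_truth.yaml` (when
simulating), `de_results.tsv` / `candidates.txt`,
`criticality_profile.tsv` (timepoint, size, SD_in, PCC_in, PCC_out, CI),
`dnb_members.tsv` (gene, index_one, index_two, integrated_index, rank),
`run_config.yaml`, and `manifest.json`. Outputs are byte-identical across
reruns with the same config and seed. The stages compose: e.g.

```bash
dnbkit simulate --config config.yaml --seed 7 --out-dir out/
dnbkit screen   --matrix out/expression.tsv --metadata out/samples.tsv --scale log --out-dir out/
dnbkit dnb      --matrix out/expression.tsv --metadata out/samples.tsv --scale log \
                --candidates out/candidates.txt --out-dir out/
dnbkit rank     --members out/dnb_group.txt --network net.tsv --gmt sets.gmt \
                --total-pathways 185 --out-dir out/
```

## Notes on interpretation

* Correlations are computed across replicates within one timepoint. With
  very few replicates (e.g. 3) sample correlations are extremely noisy; the
  search warns below 5 replicates, and recovery guarantees in the test
  suite use 10+.
* The expression scale (`raw` vs `log`) is a user declaration; statistics
  are computed on the values as given, never transformed implicitly.
* `PCC_out`'s background defaults to all measured genes outside the group;
  `--background candidates` restricts it to the candidate set.
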