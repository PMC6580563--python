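# JSON report schema

One document per run (`<prefix>.report.json`), also embedded verbatim in
the HTML report inside `<script type="application/json" id="report-data">`.
All counters are exact integers; percentages and quality summaries are
derived floats. Positions are 1-based in derived arrays (index 0 = first
base).

```
{
  "schema_version": 1,
  "totals": {
    "reads_in":            int,   // records read (both mates combined)
    "reads_out":           int,   // records written
    "reads_filtered":      int,   // reads_in - reads_out
    "bases_in":            int,
    "bases_out":           int,
    "reads_with_adapter":  int    // reads with an adapter match removed
  },
  "per_mate_totals": [            // paired runs only, else []
    { "mate": 1, ...same keys as totals... },
    { "mate": 2, ... }
  ],
  "before": <panel>,              // statistics over input reads
  "after":  <panel>,              // statistics over written reads
  "adapter_overlap_histogram": {  // aligned adapter bases -> read count
    "<k>": int, ...
  },
  "filter_counts": {              // reads failing exactly one criterion,
    "quality_filter": int,        // plus "+" for >= 2 criteria;
    "n_ratio":        int,        // values sum to totals.reads_filtered
    "too_short":      int,
    "too_long":       int,
    "mate_failed":    int,
    "+":              int
  }
}
```

Each `<panel>`:

```
{
  "reads": int,
  "bases": int,
  "length_histogram": { "<length>": int, ... },      // sums to reads
  "per_position_quality_counts": [[int; 94]; npos],  // counts per Phred 0..93
  "per_position_base_counts": { "A": [int; npos], "C": ..., "G": ...,
                                "T": ..., "N": ... },
  "per_position_quality": {                          // derived from counts
    "min": [float; npos], "q1": ..., "median": ..., "q3": ...,
    "max": ..., "mean": ...                          // linear-interp quartiles
  },
  "base_percent": { "A": float, ..., "N": float }    // sums to 100.0
}
```

`RunStats.from_dict` reconstructs the accumulators from the raw count
fields; the derived fields are recomputed, so JSON round-trips are
lossless for every counter.
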