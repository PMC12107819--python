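# elnbridge

Research groups rarely live inside a single Electronic Lab Notebook.  A
chemistry lab may document reactions in a chemistry-specific ELN (Chemotion
style: entries carry their fields under `properties.*` and are organized in
*collections*), while the materials-science lab next door documents
fabrication and characterization in a form-driven ELN (Herbie style: fields
under `values.*`, no collections).  The same physical sample — say a polymer
membrane that is fabricated in one lab and chemically post-modified in the
other — then exists as two records in two systems that do not talk to each
other, and there is no standard protocol for moving structured entries
between ELNs.

`elnbridge` is a synchronization hub for exactly this situation.  Instead of
a common exchange file format, it moderates the two platforms' APIs through
pluggable adapters (*delegates*) and keeps configured entry types
bidirectionally in sync:

* a **sync model** pairs one input mask (entry type) per platform — e.g.
  `reaction` ↔ `post-modification` — and names a per-side **sync key** path
  (`properties.name` / `values.reaction_name`) whose equal values identify
  an entry pair;
* **mappings** connect individual fields.  *Atomic* mappings copy one value,
  optionally through a **transfer operator** (a small serializable
  expression: date-time re-patterning, choice-label remaps, casts,
  arithmetic, string splits); *array* mappings apply submappings
  element-wise to lists;
* each run detects changes by comparing current values against the
  **snapshots** stored at the last synchronization of each pair (robust to
  clock skew between platforms), creates missing counterpart entries where
  the target platform's settings allow it, and transfers values.  Conflicts
  are resolved **last-write-wins**: when both sides of a pair changed, the
  entry with the later update timestamp overwrites all mapped fields of its
  partner;
* a **dry-run test mode** simulates either direction independently without
  writing anything, and an **autosync** loop repeats the run on a fixed
  interval.  Every applied change is recorded in an append-only JSON-lines
  process log.

Two in-memory mock platforms (Chemotion-like and Herbie-like) ship with the
package, so the entire workflow — including a worked membrane
post-modification example — runs offline.  A generic REST delegate skeleton
shows how a real platform adapter plugs in.

## Worked example: membrane post-modification

Before the first sync, the Herbie-like platform documents a fabricated
membrane (a `product` named `PAN$20/013-PAN-EDA-01;`) plus an empty
`post-modification` form, and the Chemotion-like platform holds the
filled-in `reaction`.  Write a config and drive it from the shell:

```python
from elnbridge.datamodel import save_config
from elnbridge.fixtures import build_membrane_config

cfg = build_membrane_config(
    endpoint_a="mock:membrane-chemotion@chem.json",
    endpoint_b="mock:membrane-herbie@herbie.json",
    state_path="state.json", log_path="log.jsonl")
save_config(cfg, "bridge.yaml")
```

```console
$ elnbridge validate -c bridge.yaml
2 sync model(s), 0 error(s), 0 warning(s)

$ elnbridge test -c bridge.yaml "Post-modification of membranes" --direction ab
object 'PM-PAN-EDA-01', direction a_to_b:
  Weight: None -> 250
  Conditions: None -> 'EDA in water, reflux 2 h (synthetic fixture)'
  Status: None -> 'In Progress'
  ...
  Time: None -> '2 h'

$ elnbridge sync -c bridge.yaml
Post-modification of membranes [run-0001]: 12 update(s), 0 creation(s), 1 skip(s), 0 error(s)
Membrane products [run-0002]: 0 update(s), 1 creation(s), 0 skip(s), 0 error(s)

$ elnbridge sync -c bridge.yaml
Post-modification of membranes [run-0003]: 0 update(s), 0 creation(s), 1 skip(s), 0 error(s)
Membrane products [run-0004]: 0 update(s), 0 creation(s), 1 skip(s), 0 error(s)
```

Reading the output: the dry run lists, per mapping, the old and new value
the transfer would write into the Herbie-like form — note the `Status`
choice label translated (`running` → `In Progress`) and the date re-patterned
by the transfer operators.  The first real run fills the
`post-modification` form (12 field updates) and creates the membrane as a
Chemotion-like `sample` (1 creation); the second run applies nothing, because
nothing changed since the snapshots were taken — synchronization is
idempotent.  If the chemist then edits the employed membrane weight, the
reaction conditions and the reaction status, the next run propagates exactly
those three field updates.

The same flow is available as a library: `plan_sync` (side-effect-free
plan), `apply_plan`, `simulate`, `run_autosync` in `elnbridge.engine`.

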