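"""Brute-force reference implementation of the staircase rules, kept deliberately
independent of dimvision.staircase: a plain loop over outcomes applying the
trial-unit rules as stated, used to cross-check the controller trajectory."""


def oracle_trajectory(outcomes, schedule):
    """Return (per-trial levels, reversal values, completed-unit sizes).

    Two consecutive corrects at a level -> one step harder; an incorrect (alone
    or after one correct) -> one step easier; a reversal is a completed unit
    whose outcome differs from the previous completed unit's, valued at the
    level the unit was run; the step in force is set by the reversal count
    before the current unit's reversal is recorded; levels clamp at the bounds.
    """
    level = schedule.start_level
    levels, reversal_values, unit_sizes = [], [], []
    pending = False
    last_outcome = None
    n_rev = 0
    size = 0
    for c in outcomes:
        levels.append(level)
        size += 1
        if c and not pending:
            pending = True
            continue
        outcome = "S" if c else "U"
        pending = False
        unit_sizes.append(size)
        size = 0
        idx = sum(1 for b in schedule.breakpoints if n_rev >= b)
        step = schedule.steps[idx]
        if last_outcome is not None and outcome != last_outcome:
            reversal_values.append(level)
            n_rev += 1
        last_outcome = outcome
        sign = schedule.harder_direction if outcome == "S" else -schedule.harder_direction
        level = min(max(level + sign * step, schedule.floor_level), schedule.ceiling_level)
    return levels, reversal_values, unit_sizes
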