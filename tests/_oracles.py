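"""Independent brute-force oracles shared across test modules."""

__all__ = ["oracle_events"]


def oracle_events(values, threshold, need):
    """Run-length enumeration of sub-threshold runs of length >= need.

    Returns a list of (start_index, run_length) pairs. Deliberately written
    as a plain scan so it shares no code with the detector it checks.
    """
    runs, i = [], 0
    n = len(values)
    while i < n:
        if values[i] <= threshold:
            j = i
            while j + 1 < n and values[j + 1] <= threshold:
                j += 1
            if j - i + 1 >= need:
                runs.append((i, j - i + 1))
            i = j + 1
        else:
            i += 1
    return runs
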