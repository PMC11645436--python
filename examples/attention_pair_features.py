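"""Extract the attention-map pair feature for two PTM sites.

A protein language model with 33 layers x 20 heads yields 660 L x L
attention maps per sequence; for a site pair (i, j) the two scores A[i,j]
and A[j,i] from every map form a 1320-long feature vector. Here the
deterministic synthetic provider stands in for the language model.
"""

from ptmct import attention_maps, make_synthetic_provider, \
    pair_attention_vector

provider = make_synthetic_provider(seed=7)
sequence = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"

stack = attention_maps(provider, sequence)
vector = pair_attention_vector(stack, 5, 17)

print(f"sequence length      : {len(sequence)}")
print(f"attention maps       : {stack.n_layers} layers x {stack.n_heads} "
      f"heads = {stack.n_layers * stack.n_heads}")
print(f"pair feature length  : {len(vector.values)}")
print(f"first map (A_ij, A_ji): ({vector.values[0]:.4f}, "
      f"{vector.values[1]:.4f})")
# The two entries per map differ because attention is asymmetric; their
# magnitude (~1/L for an unbiased map) scores how strongly the model links
# the two positions.
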