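(ostrich:100,((duck:65,(chicken:30,turkey:30)galliform_ancestor:35)galloanserae_ancestor:30,(zebra_finch:54,budgerigar:54)passerea_ancestor:41)neognath_ancestor:5)avian_ancestor;
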