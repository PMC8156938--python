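{
 "complexation_thermo.tsv": "a5a1ae6fdf5035afc9470817daed04537257392f23fd5df46b57fd74a37001e3",
 "eda_components.tsv": "da0bca538e87f914ee67fc150338f9a76b80a4108afe37eda7be2cb9f36171c6",
 "frontier_descriptors.tsv": "7de9f898bfa7ca7e98a6cfbdfebc16ffe75241b7d2e84193c0af6a71630616fd",
 "nbo_interactions.tsv": "30d77e185929eab756cb7136bbc14366a04650158762583db745f607f99639f5"
}
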