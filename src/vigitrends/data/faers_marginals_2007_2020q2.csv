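drug,category,n_drug,n_category,n_combination,n_total
pregabalin,drug_abuse_and_dependence,107905,118980,4558,7430750
pregabalin,drug_withdrawal,107905,28149,1463,7430750
pregabalin,overdose,107905,85274,2053,7430750
pregabalin,tolerance,107905,1965,128,7430750
pregabalin,euphoria,107905,280097,10664,7430750
gabapentin,drug_abuse_and_dependence,102386,118980,2924,7430750
gabapentin,drug_withdrawal,102386,28149,796,7430750
gabapentin,overdose,102386,85274,1904,7430750
gabapentin,tolerance,102386,1965,98,7430750
gabapentin,euphoria,102386,280097,7644,7430750
levetiracetam,drug_abuse_and_dependence,43842,118980,767,7430750
levetiracetam,drug_withdrawal,43842,28149,254,7430750
levetiracetam,overdose,43842,85274,979,7430750
levetiracetam,tolerance,43842,1965,9,7430750
levetiracetam,euphoria,43842,280097,2077,7430750
clonazepam,drug_abuse_and_dependence,55856,118980,3700,7430750
clonazepam,drug_withdrawal,55856,28149,976,7430750
clonazepam,overdose,55856,85274,2588,7430750
clonazepam,tolerance,55856,1965,98,7430750
clonazepam,euphoria,55856,280097,4765,7430750
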