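# Default vocabulary: four study drugs and five abuse-related term categories.
#
# The pt_list entries for the two SMQ-labelled categories
# (drug_abuse_and_dependence, drug_withdrawal) are PLACEHOLDER lists of
# plausible narrow-scope PTs.  They are NOT the licensed MedDRA SMQ
# membership, which is proprietary; licence holders should supply their own
# vocabulary file to override them.  The tolerance, overdose and euphoria
# categories are fully enumerated PT lists and need no licence.
drugs:
  - generic_name: pregabalin
    brand_names: [lyrica]
  - generic_name: gabapentin
    brand_names: [neurontin]
  - generic_name: clonazepam
    brand_names: [klonopin]
  # "kepra" is kept as printed in the source dictionary; "keppra" is the
  # marketed spelling and is added as an alias.  Both map to levetiracetam.
  - generic_name: levetiracetam
    brand_names: [kepra, keppra]

categories:
  - name: drug_abuse_and_dependence
    scope: primary
    # placeholder for the narrow-scope SMQ "drug abuse and dependence"
    pt_list:
      - drug abuse
      - drug abuser
      - drug dependence
      - drug use disorder
      - substance abuse
      - substance abuser
      - substance use disorder
      - dependence
      - drug addiction
      - polysubstance abuse
      - intentional product misuse
      - drug diversion
  - name: drug_withdrawal
    scope: secondary
    # placeholder for the narrow-scope SMQ "drug withdrawal"
    pt_list:
      - drug withdrawal syndrome
      - withdrawal syndrome
      - drug withdrawal convulsions
      - drug withdrawal headache
      - drug withdrawal syndrome neonatal
      - rebound effect
      - steroid withdrawal syndrome
  - name: tolerance
    scope: secondary
    pt_list:
      - drug tolerance
      - drug tolerance increased
  - name: overdose
    scope: secondary
    pt_list:
      - overdose
      - intentional overdose
  - name: euphoria
    scope: secondary
    pt_list:
      - euphoric mood
      - feeling abnormal
      - feeling drunk
      - feeling of relaxation
      - dizziness
      - thinking abnormal
      - hallucination
      - inappropriate affect

query_term_sets:
  - name: drug_abuse_and_dependence
    search_terms: [abuse, dependence]
  - name: drug_withdrawal
    search_terms: [withdrawal]
  - name: overdose
    search_terms: [overdose]
  - name: tolerance
    search_terms: [tolerance]
  # "high" is the search-domain counterpart of the euphoria event category
  - name: euphoria
    search_terms: [high]
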