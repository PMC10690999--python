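# WHO European Region nutrient profile model, first edition (2015).
# One entry per category; maxima are per 100 g (solids) or per 100 ml
# (beverages), in the units of the nutrient key. permission_mode:
#   never_permitted    -> marketing to children never permitted
#   always_permitted   -> always permitted, no composition test
#   threshold_evaluated-> permitted only if every criterion is met
model_name: "WHO European Region nutrient profile model"
version: "who_euro_2015"
categories:
  - category_code: confectionery
    label: "Chocolate and sugar confectionery, energy bars, sweet toppings and desserts"
    permission_mode: never_permitted
  - category_code: sweet_bakery
    label: "Cakes, sweet biscuits and pastries, other sweet bakery wares"
    permission_mode: never_permitted
  - category_code: savoury_snacks
    label: "Savoury snacks"
    permission_mode: threshold_evaluated
    maxima:
      total_sugars_g: 10
      salt_g: 0.1
  - category_code: juices
    label: "Juices (100% fruit and vegetable juices, smoothies and concentrates)"
    permission_mode: never_permitted
  - category_code: milk_drinks
    label: "Milk drinks"
    permission_mode: threshold_evaluated
    maxima:
      total_fat_g: 2.5
    forbid_added_sugars: true
    forbid_nss: true
  - category_code: energy_drinks
    label: "Energy drinks"
    permission_mode: never_permitted
  - category_code: other_beverages
    label: "Other beverages (soft drinks, waters and other drinks)"
    permission_mode: threshold_evaluated
    forbid_added_sugars: true
    forbid_nss: true
  - category_code: edible_ices
    label: "Edible ices, ice cream and frozen desserts"
    permission_mode: never_permitted
  - category_code: breakfast_cereals
    label: "Breakfast cereals"
    permission_mode: threshold_evaluated
    maxima:
      total_fat_g: 10
      total_sugars_g: 15
      salt_g: 1.6
  - category_code: yoghurts_creams
    label: "Yoghurts, sour milk, cream and similar foods"
    permission_mode: threshold_evaluated
    maxima:
      total_fat_g: 2.5
      saturated_fat_g: 2.0
      total_sugars_g: 10
      salt_g: 0.2
  - category_code: cheese
    label: "Cheese"
    permission_mode: threshold_evaluated
    maxima:
      total_fat_g: 20
      salt_g: 1.3
  - category_code: ready_made_foods
    label: "Ready-made and convenience foods and composite dishes"
    permission_mode: threshold_evaluated
    maxima:
      energy_kcal: 225
      total_fat_g: 10
      saturated_fat_g: 4
      total_sugars_g: 10
      salt_g: 1.0
  - category_code: butter_fats_oils
    label: "Butter and other fats and oils"
    permission_mode: threshold_evaluated
    maxima:
      saturated_fat_g: 20
      salt_g: 1.3
  - category_code: bread_products
    label: "Bread, bread products and crisp breads"
    permission_mode: threshold_evaluated
    maxima:
      total_fat_g: 10
      total_sugars_g: 10
      salt_g: 1.2
  - category_code: pasta_rice_grains
    label: "Fresh or dried pasta, rice and grains"
    permission_mode: threshold_evaluated
    maxima:
      total_fat_g: 10
      total_sugars_g: 10
      salt_g: 1.2
  - category_code: fresh_frozen_meat_fish
    label: "Fresh and frozen meat, poultry, fish and similar"
    permission_mode: always_permitted
  - category_code: processed_meat_fish
    label: "Processed meat, poultry, fish and similar"
    permission_mode: threshold_evaluated
    maxima:
      total_fat_g: 20
      salt_g: 1.7
  - category_code: fresh_frozen_fruit_veg
    label: "Fresh and frozen fruit, vegetables and legumes"
    permission_mode: always_permitted
  - category_code: processed_fruit_veg
    label: "Processed fruit, vegetables and legumes"
    permission_mode: threshold_evaluated
    maxima:
      total_fat_g: 5
      salt_g: 1.0
    forbid_added_sugars: true
  - category_code: sauces_dips_dressings
    label: "Sauces, dips and dressings"
    permission_mode: threshold_evaluated
    maxima:
      total_fat_g: 10
      total_sugars_g: 10
      salt_g: 1.0
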